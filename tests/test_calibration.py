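"""Cost calibration against published totals; fixtures; life tables."""

import dataclasses

import numpy as np
import pytest

from gcsfcea import (
    CalibrationError,
    CalibrationTarget,
    GompertzLifeTableSpec,
    build_scenario,
    calibrate_costs,
    cost_coefficients,
    datasets,
    generate_life_table,
    incremental,
    load_life_table,
    run_base_case,
    run_strategy,
    save_life_table,
)


class TestCalibrateCosts:
    def test_synthetic_round_trip_recovers_known_costs(self):
        cfg = build_scenario("Austria", "BC", "filgrastim", calibrate=False)
        known = dataclasses.replace(
            cfg.costs, gcsf_cost_per_cycle=321.0, fn_hospitalisation_cost=5432.1
        )
        cfg_known = dataclasses.replace(cfg, costs=known)
        pp = run_strategy(cfg_known, "PP", with_avoided=False)
        sp = run_strategy(cfg_known, "SP", with_avoided=False)
        target = CalibrationTarget("Austria", "BC", "filgrastim",
                                   pp_cost=pp.cost, sp_cost=sp.cost)
        solved = calibrate_costs(target, cfg)
        assert solved.cycle_drug_cost() == pytest.approx(321.0, abs=1e-6)
        assert solved.fn_hospitalisation_cost == pytest.approx(5432.1, abs=1e-6)

    def test_published_austria_bc_totals_reproduced(self, bc_austria):
        res = run_base_case(bc_austria)
        assert res["PP"].cost == pytest.approx(1567.0, abs=0.5)
        assert res["SP"].cost == pytest.approx(980.0, abs=0.5)

    def test_equal_totals_remain_solvable(self):
        cfg = build_scenario("Austria", "BC", "filgrastim", calibrate=False)
        target = CalibrationTarget("Austria", "BC", "filgrastim",
                                   pp_cost=1500.0, sp_cost=1500.0)
        solved = calibrate_costs(target, cfg)
        assert solved.fn_hospitalisation_cost > 0
        assert solved.cycle_drug_cost() > 0

    def test_inconsistent_totals_raise(self):
        cfg = build_scenario("Austria", "BC", "filgrastim", calibrate=False)
        # an SP total far above any attainable with non-negative costs
        target = CalibrationTarget("Austria", "BC", "filgrastim",
                                   pp_cost=10.0, sp_cost=50_000.0)
        with pytest.raises(CalibrationError, match="negative"):
            calibrate_costs(target, cfg)

    def test_coefficients_are_expected_discounted_counts(self, bc_austria):
        a_pp, b_pp = cost_coefficients(bc_austria, "PP")
        a_sp, b_sp = cost_coefficients(bc_austria, "SP")
        # PP delivers prophylaxis nearly every cycle; SP only after an event
        assert a_pp > 5.0 and a_pp <= bc_austria.cohort.n_cycles
        assert 0 < a_sp < 1.0
        # PP prevents events, so its discounted FN count is smaller
        assert 0 < b_pp < b_sp < 1.0


class TestFixtures:
    def test_full_grid_of_fixtures_exists(self, all_fixtures):
        assert len(all_fixtures) == 18
        ids = set(all_fixtures)
        assert ids == set(datasets.fixture_ids())

    def test_france_nsclc_filgrastim_base_case_dominant(self, nsclc_france):
        res = run_base_case(nsclc_france)
        assert incremental(res["PP"], res["SP"]).status == "dominant"

    def test_german_incremental_costs_highest_for_filgrastim(self, all_fixtures):
        for cancer in datasets.CANCERS:
            deltas = {}
            for country in datasets.COUNTRIES:
                cfg = all_fixtures[datasets.fixture_id(country, cancer, "filgrastim")]
                res = run_base_case(cfg)
                deltas[country] = res["PP"].cost - res["SP"].cost
            assert deltas["Germany"] > deltas["Austria"]
            assert deltas["Germany"] > deltas["France"]

    def test_solved_filgrastim_costs_in_list_price_band(self, all_fixtures):
        for sid, cfg in all_fixtures.items():
            if cfg.costs.agent != "filgrastim":
                continue
            per_cycle = cfg.costs.cycle_drug_cost()
            assert 55.54 <= per_cycle <= 20 * 55.54, sid


class TestLifeTables:
    def test_vanishing_baseline_hazard_gives_zero_mortality(self):
        spec = GompertzLifeTableSpec(a=1e-300, b=0.09, terminal_age=100)
        lt = generate_life_table(spec)
        assert np.all(lt.qx_female[:-1] == 0.0)
        assert lt.qx_female[-1] == 1.0

    def test_qx_monotone_in_age(self):
        lt = generate_life_table(GompertzLifeTableSpec(a=2e-5, b=0.1))
        assert np.all(np.diff(lt.qx_female) >= 0)
        assert np.all(np.diff(lt.qx_male) >= 0)
        assert np.all(lt.qx_male[:-1] >= lt.qx_female[:-1])

    def test_csv_round_trip(self, tmp_path):
        lt = generate_life_table(GompertzLifeTableSpec(a=2.4e-5, b=0.095))
        path = tmp_path / "lt.csv"
        save_life_table(lt, path)
        again = load_life_table(path)
        assert np.allclose(again.qx_female, lt.qx_female)
        assert np.allclose(again.qx_male, lt.qx_male)

    def test_life_expectancy_two_ways_agree(self, bc_austria):
        # direct survival sum vs the cohort engine with zero disease risk
        from gcsfcea.cohort import DAYS_PER_YEAR, run_post_chemo_phase, ChemoState

        lt = generate_life_table(GompertzLifeTableSpec(a=2.4e-5, b=0.095,
                                                       male_factor=1.7))
        cfg = dataclasses.replace(
            bc_austria,
            cohort=dataclasses.replace(bc_austria.cohort, entry_age=60.0,
                                       n_cycles=1, cycle_length_days=1e-9),
            mortality=dataclasses.replace(bc_austria.mortality,
                                          cancer_annual_mortality=0.0),
            costs=dataclasses.replace(bc_austria.costs, los_days=0.0),
            discount_rate_effects=0.0,
            life_table=lt,
        )
        entry = ChemoState(alive_no_hist=1.0, alive_hist=0.0, dead=0.0, cycle=1)
        ly, _ = run_post_chemo_phase(cfg, entry)
        qx = lt.qx("f")
        n_years = lt.terminal_age - 60
        q = qx[60 : 60 + n_years].copy()
        q[-1] = 1.0
        direct = np.cumprod(1 - q).sum()
        assert ly == pytest.approx(direct, abs=1e-9)
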