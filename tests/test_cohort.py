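"""Cohort engine: conversions, conservation, discounting, phases, oracle."""

import dataclasses

import numpy as np
import pytest

from gcsfcea import (
    ChemoState,
    LifeTable,
    ValidationError,
    annual_prob_from_5yr_death,
    run_base_case,
    run_chemo_phase,
    run_post_chemo_phase,
    run_strategy,
    simulate_individuals,
)
from gcsfcea.cohort import DAYS_PER_YEAR, _post_chemo_survival
from gcsfcea.risk import CycleRiskTable

NULL_RISKS = CycleRiskTable(p_cycle1=0.0, p_later_no_hist=0.0, p_later_hist=0.0)


def flat_life_table(q, terminal=110):
    qx = np.full(terminal + 1, q)
    qx[-1] = 1.0
    return LifeTable(qx_female=qx, qx_male=qx)


def make_flat_cfg(bc_austria, q=0.03, d=0.03, cancer_mort=0.0):
    return dataclasses.replace(
        bc_austria,
        life_table=flat_life_table(q),
        discount_rate_costs=d,
        discount_rate_effects=d,
        mortality=dataclasses.replace(
            bc_austria.mortality, cancer_annual_mortality=cancer_mort
        ),
    )


class TestMortalityConversion:
    def test_zero_risk_maps_to_zero(self):
        assert annual_prob_from_5yr_death(0.0, 5) == 0.0

    def test_round_trip_identity(self):
        for p5 in (0.05, 0.28, 0.7, 0.99):
            p1 = annual_prob_from_5yr_death(p5, 5)
            assert 1 - (1 - p1) ** 5 == pytest.approx(p5, abs=1e-12)

    def test_published_nhl_value_inverts_consistently(self):
        # annual 0.0652 corresponds to a 5-year probability it reproduces
        p5 = 1 - (1 - 0.0652) ** 5
        assert annual_prob_from_5yr_death(p5, 5) == pytest.approx(0.0652, abs=1e-12)

    def test_certain_death_rejected(self):
        with pytest.raises(ValidationError):
            annual_prob_from_5yr_death(1.0, 5)


class TestChemoPhase:
    def test_null_risk_gives_no_events_or_deaths(self, bc_austria):
        st = run_chemo_phase(bc_austria, "PP", risks=NULL_RISKS)
        assert st.dead == 0.0
        assert st.fn_events == 0.0
        assert st.alive_no_hist == pytest.approx(1.0, abs=1e-12)

    def test_no_effect_agent_equalises_events_not_costs(self, bc_austria):
        cfg = dataclasses.replace(
            bc_austria,
            clinical=dataclasses.replace(bc_austria.clinical, rr_gcsf=1 - 1e-12),
        )
        pp = run_chemo_phase(cfg, "PP")
        sp = run_chemo_phase(cfg, "SP")
        assert pp.fn_events == pytest.approx(sp.fn_events, abs=1e-9)
        assert pp.fn_deaths == pytest.approx(sp.fn_deaths, abs=1e-9)
        assert pp.cost > sp.cost  # PP still pays for the drug every cycle

    def test_occupancy_conserved_each_cycle(self, all_fixtures):
        for cfg in all_fixtures.values():
            for strategy in ("PP", "SP", "NONE"):
                st = run_chemo_phase(cfg, strategy)
                total = st.alive_no_hist + st.alive_hist + st.dead
                assert total == pytest.approx(1.0, abs=1e-12)
                assert min(st.alive_no_hist, st.alive_hist, st.dead) >= 0.0

    def test_occupancy_drift_detected(self):
        st = ChemoState(alive_no_hist=0.6, alive_hist=0.3, dead=0.2, cycle=1)
        with pytest.raises(ValidationError, match="occupancy"):
            st.check()


class TestPostChemoPhase:
    def test_flat_hazard_matches_annuity_closed_form(self, bc_austria):
        q, d = 0.03, 0.05
        cfg = make_flat_cfg(bc_austria, q=q, d=d)
        entry = ChemoState(alive_no_hist=1.0, alive_hist=0.0, dead=0.0,
                           cycle=cfg.cohort.n_cycles)
        ly, _ = run_post_chemo_phase(cfg, entry)
        t0 = cfg.cohort.n_cycles * cfg.cohort.cycle_length_days / DAYS_PER_YEAR
        terminal = 110
        n_years = terminal - int(round(cfg.cohort.entry_age))
        k = np.arange(1, n_years + 1)
        surv = (1 - q) ** k
        surv[-1] = 0.0  # terminal age absorbs the cohort
        closed = np.sum(surv / (1 + d) ** (t0 + k - 0.5))
        assert ly == pytest.approx(closed, abs=1e-9)

    def test_unit_hazard_ratio_makes_strata_identical(self, bc_austria):
        cfg = dataclasses.replace(
            bc_austria,
            mortality=dataclasses.replace(bc_austria.mortality, hr_low_rdi=1.0),
        )
        entry = ChemoState(alive_no_hist=0.8, alive_hist=0.2, dead=0.0, cycle=6)
        base_ly, base_q = run_post_chemo_phase(cfg, entry)
        # collapsing everyone into one stratum changes nothing when HR = 1
        cfg_all_low = dataclasses.replace(
            cfg, clinical=dataclasses.replace(cfg.clinical, p_low_rdi_no_fn=1.0,
                                              p_low_rdi_fn=1.0),
        )
        ly2, q2 = run_post_chemo_phase(cfg_all_low, entry)
        assert ly2 == pytest.approx(base_ly, abs=1e-12)
        assert q2 == pytest.approx(base_q, abs=1e-12)

    def test_low_rdi_stratum_survives_less(self, all_fixtures):
        cfg = all_fixtures["austria_nhl_filgrastim"]
        from gcsfcea.lifetables import resolve_life_table

        qx = resolve_life_table(cfg.life_table).qx("f")
        excess = cfg.mortality.cancer_annual_mortality
        hr = cfg.mortality.hr_low_rdi
        s_low = _post_chemo_survival(qx, 62, excess * hr, 20)
        s_high = _post_chemo_survival(qx, 62, excess, 20)
        assert s_low.sum() < s_high.sum()

    def test_cure_reverts_to_background_mortality(self, bc_austria):
        cfg = make_flat_cfg(bc_austria, q=0.02, cancer_mort=0.0)
        from gcsfcea.lifetables import resolve_life_table

        qx = resolve_life_table(cfg.life_table).qx("f")
        surv = _post_chemo_survival(qx, 50, 0.05, 20)
        bare = np.cumprod(1 - qx[50 : qx.size - 1 + 1][: surv.size])
        # beyond the cure horizon the survival ratio is frozen
        # (excluding the forced-absorption terminal year)
        ratios = surv[20:-1] / bare[20:-1]
        assert np.allclose(ratios, ratios[0], atol=1e-12)


class TestRunStrategy:
    def test_zero_risk_zero_cost_reproduces_life_expectancy(self, bc_austria):
        cfg = make_flat_cfg(bc_austria, q=0.03, d=0.0, cancer_mort=0.0)
        cfg = dataclasses.replace(
            cfg,
            costs=dataclasses.replace(cfg.costs, gcsf_cost_per_cycle=0.0,
                                      fn_hospitalisation_cost=0.0,
                                      drug_unit_price=0.0),
        )
        out = run_strategy(cfg, "PP", risks=NULL_RISKS)
        assert out.cost == 0.0
        t_chemo = cfg.cohort.n_cycles * cfg.cohort.cycle_length_days / DAYS_PER_YEAR
        n_years = 110 - 50
        surv = (1 - 0.03) ** np.arange(1, n_years + 1)
        surv[-1] = 0.0
        assert out.ly == pytest.approx(t_chemo + surv.sum(), abs=1e-9)

    def test_pp_prevents_more_events_than_sp(self, all_fixtures):
        for cfg in all_fixtures.values():
            pp = run_strategy(cfg, "PP")
            sp = run_strategy(cfg, "SP")
            assert pp.fn_events < sp.fn_events
            assert pp.fn_events_avoided > sp.fn_events_avoided
            assert pp.qaly <= pp.ly and sp.qaly <= sp.ly

    def test_hospitalisation_cost_hits_sp_harder(self, all_fixtures):
        for cfg in all_fixtures.values():
            doubled = dataclasses.replace(
                cfg,
                costs=dataclasses.replace(
                    cfg.costs,
                    fn_hospitalisation_cost=2 * cfg.costs.fn_hospitalisation_cost,
                ),
            )
            d_pp = run_strategy(doubled, "PP").cost - run_strategy(cfg, "PP").cost
            d_sp = run_strategy(doubled, "SP").cost - run_strategy(cfg, "SP").cost
            assert d_sp > d_pp

    def test_discounting_monotone(self, bc_austria):
        undisc = dataclasses.replace(bc_austria, discount_rate_costs=0.0,
                                     discount_rate_effects=0.0)
        lo = dataclasses.replace(bc_austria, discount_rate_costs=0.02,
                                 discount_rate_effects=0.02)
        hi = dataclasses.replace(bc_austria, discount_rate_costs=0.06,
                                 discount_rate_effects=0.06)
        outs = [run_strategy(c, "PP") for c in (undisc, lo, hi)]
        for a, b in zip(outs, outs[1:]):
            assert a.cost > b.cost
            assert a.ly > b.ly
            assert a.qaly > b.qaly

    def test_deterministic_and_reference_run_consistent(self, bc_austria):
        a = run_strategy(bc_austria, "SP")
        b = run_strategy(bc_austria, "SP")
        assert a == b
        res = run_base_case(bc_austria)
        assert res["PP"].fn_events_avoided == pytest.approx(
            res["NONE"].fn_events - res["PP"].fn_events
        )


class TestMicrosimOracle:
    def test_same_seed_reproduces(self, bc_austria):
        a = simulate_individuals(bc_austria, "PP", 2000, seed=3)
        b = simulate_individuals(bc_austria, "PP", 2000, seed=3)
        assert a.outcome == b.outcome

    def test_degenerate_single_patient_matches_cohort(self, bc_austria):
        # with zero FN risk and a deterministic life table the single
        # simulated patient is the cohort expectation
        cfg = make_flat_cfg(bc_austria, q=0.0, cancer_mort=0.0)
        cohort = run_strategy(cfg, "NONE", risks=NULL_RISKS, with_avoided=False)
        micro = simulate_individuals(
            dataclasses.replace(
                cfg, clinical=dataclasses.replace(cfg.clinical,
                                                  baseline_fn_risk=1e-15)
            ),
            "NONE", 1, seed=0,
        )
        assert micro.outcome.fn_events == 0.0
        assert micro.outcome.cost == cohort.cost
        assert micro.outcome.ly == pytest.approx(cohort.ly, abs=1e-9)

    def test_cohort_within_monte_carlo_error(self, bc_austria):
        cohort = run_strategy(bc_austria, "SP", with_avoided=False)
        micro = simulate_individuals(bc_austria, "SP", 200_000, seed=11)
        for fld in ("cost", "ly", "qaly", "fn_events", "fn_deaths"):
            se = micro.se[fld]
            assert abs(getattr(cohort, fld) - getattr(micro.outcome, fld)) < 3 * se
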