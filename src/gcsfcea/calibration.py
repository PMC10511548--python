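"""Cost calibration against published base-case totals and fixture building.

The original analysis published its clinical inputs and its base-case
totals, but not the country cost tables behind them.  Because the model's
total discounted cost under either strategy is exactly linear in the two
unknown cost inputs —

    total(strategy) = A(strategy) * gcsf_cost_per_cycle
                    + B(strategy) * fn_hospitalisation_cost

where A is the expected discounted number of prophylaxis cycles delivered
and B the expected discounted number of FN admissions — the pair can be
identified from the printed PP and SP totals by a 2x2 linear solve.  The
clinical inputs are never touched.  ``build_fixtures`` runs this for every
country x cancer x agent block and emits the 18 bundled scenario files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import datasets
from .cohort import run_chemo_phase
from .errors import CalibrationError
from .lifetables import GompertzLifeTableSpec, generate_life_table
from .params import (
    ClinicalParams,
    CohortProfile,
    CostParams,
    MortalityParams,
    ScenarioConfig,
    UncertainParameter,
    UtilityParams,
    save_scenario,
)
from .risk import build_risk_table

__all__ = [
    "CalibrationTarget",
    "cost_coefficients",
    "calibrate_costs",
    "build_scenario",
    "build_fixtures",
    "generate_life_table",
    "GompertzLifeTableSpec",
]

_MAX_CONDITION = 1e6
_SANITY_BAND = (1.0, 20.0)  # filgrastim per-cycle cost vs the EUR 55.54 list price
_FILGRASTIM_LIST_PRICE = 55.54


@dataclass(frozen=True)
class CalibrationTarget:
    """Published totals for one country x cancer x agent block."""

    country: str
    cancer: str
    agent: str
    pp_cost: float
    sp_cost: float
    pp_fn_avoided: Optional[float] = None
    sp_fn_avoided: Optional[float] = None
    pp_ly: Optional[float] = None
    sp_ly: Optional[float] = None
    pp_qaly: Optional[float] = None
    sp_qaly: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("pp_cost", "sp_cost"):
            if getattr(self, name) < 0:
                raise CalibrationError(f"{name}: must be >= 0")

    @classmethod
    def from_published(cls, country: str, cancer: str, agent: str) -> "CalibrationTarget":
        pp = datasets.base_case_row(country, cancer, agent, "PP")
        sp = datasets.base_case_row(country, cancer, agent, "SP")
        return cls(
            country=country, cancer=cancer, agent=agent,
            pp_cost=pp["cost"], sp_cost=sp["cost"],
            pp_fn_avoided=pp["fn_events_avoided"], sp_fn_avoided=sp["fn_events_avoided"],
            pp_ly=pp["ly"], sp_ly=sp["ly"], pp_qaly=pp["qaly"], sp_qaly=sp["qaly"],
        )


def cost_coefficients(cfg: ScenarioConfig, strategy: str) -> tuple[float, float]:
    """(A, B): expected discounted prophylaxis cycles and FN admissions.

    Obtained by running the chemotherapy phase with unit costs, exploiting
    the engine's linearity in the two cost inputs.
    """
    risks = build_risk_table(cfg.clinical, cfg.cohort.n_cycles)
    unit_drug = dataclasses.replace(
        cfg, costs=dataclasses.replace(
            cfg.costs, gcsf_cost_per_cycle=1.0, fn_hospitalisation_cost=0.0,
            drug_unit_price=0.0)
    )
    unit_hosp = dataclasses.replace(
        cfg, costs=dataclasses.replace(
            cfg.costs, gcsf_cost_per_cycle=0.0, fn_hospitalisation_cost=1.0,
            drug_unit_price=0.0)
    )
    a = run_chemo_phase(unit_drug, strategy, risks).cost
    b = run_chemo_phase(unit_hosp, strategy, risks).cost
    return a, b


def calibrate_costs(target: CalibrationTarget, cfg: ScenarioConfig) -> CostParams:
    """Solve the two cost inputs so model totals reproduce the target.

    Returns a CostParams with the solved FN hospitalisation cost and a
    drug unit price backed out of the solved per-cycle prophylaxis cost
    through the dosing rule (so weight-based OWSA stays live).
    """
    a_pp, b_pp = cost_coefficients(cfg, "PP")
    a_sp, b_sp = cost_coefficients(cfg, "SP")
    m = np.array([[a_pp, b_pp], [a_sp, b_sp]], dtype=float)
    cond = np.linalg.cond(m)
    if not np.isfinite(cond) or cond > _MAX_CONDITION:
        raise CalibrationError(
            f"{target.country}/{target.cancer}/{target.agent}: "
            f"ill-conditioned cost system (cond={cond:.3g})"
        )
    gcsf_cycle, hosp = np.linalg.solve(m, [target.pp_cost, target.sp_cost])
    if gcsf_cycle < 0 or hosp < 0:
        raise CalibrationError(
            f"{target.country}/{target.cancer}/{target.agent}: negative solved cost "
            f"(gcsf/cycle={gcsf_cycle:.2f}, hospitalisation={hosp:.2f}) — "
            "model and published totals are inconsistent"
        )
    base = cfg.costs
    unit_price = gcsf_cycle / (base.units_per_dose * base.effective_doses_per_cycle)
    return dataclasses.replace(
        base,
        drug_unit_price=float(unit_price),
        fn_hospitalisation_cost=float(hosp),
        gcsf_cost_per_cycle=None,
    )


def _uncertainty_for(
    cancer: str, agent: str, costs: CostParams, discount_rate: float
) -> tuple[UncertainParameter, ...]:
    """Published Table inputs plus fixture-chosen cost/discount ranges."""
    entries = list(datasets.clinical_inputs(cancer, agent).values())
    frac = datasets.COST_OWSA_FRACTION
    entries += [
        UncertainParameter(
            name="costs.drug_unit_price", base=costs.drug_unit_price,
            low=costs.drug_unit_price * (1 - frac),
            high=costs.drug_unit_price * (1 + frac), family="lognormal"),
        UncertainParameter(
            name="costs.fn_hospitalisation_cost", base=costs.fn_hospitalisation_cost,
            low=costs.fn_hospitalisation_cost * (1 - frac),
            high=costs.fn_hospitalisation_cost * (1 + frac), family="lognormal"),
        UncertainParameter(
            name="costs.los_days", base=costs.los_days,
            low=datasets.LOS_RANGE[0], high=datasets.LOS_RANGE[1], family="lognormal"),
        UncertainParameter(
            name="costs.patient_weight_kg", base=costs.patient_weight_kg,
            low=datasets.WEIGHT_RANGE[0], high=datasets.WEIGHT_RANGE[1],
            family="lognormal"),
        # varied in the OWSA, held at base in the PSA
        UncertainParameter(
            name="discount_rate", base=discount_rate,
            low=datasets.DISCOUNT_RANGE[0], high=datasets.DISCOUNT_RANGE[1],
            family="fixed"),
    ]
    return tuple(entries)


def build_scenario(
    country: str,
    cancer: str,
    agent: str,
    calibrate: bool = True,
) -> ScenarioConfig:
    """Assemble one scenario from published inputs and fixture settings,
    optionally calibrating the cost inputs to the published totals."""
    inputs = datasets.clinical_inputs(cancer, agent)
    cset = datasets.country_settings(country)
    cohort = CohortProfile(cancer=cancer, **datasets.cohort_profile_inputs(cancer))
    clinical = ClinicalParams(
        baseline_fn_risk=inputs["clinical.baseline_fn_risk"].base,
        rr_later_cycles=inputs["clinical.rr_later_cycles"].base,
        rr_history=inputs["clinical.rr_history"].base,
        rr_gcsf=inputs["clinical.rr_gcsf"].base,
        p_low_rdi_no_fn=inputs["clinical.p_low_rdi_no_fn"].base,
        p_low_rdi_fn=inputs["clinical.p_low_rdi_fn"].base,
        rdi_threshold_pct=datasets.RDI_THRESHOLD_PCT[cancer],
    )
    utilities = UtilityParams(
        u_chemo=inputs["utilities.u_chemo"].base,
        u_fn_hosp=inputs["utilities.u_fn_hosp"].base,
        u_post_year1=inputs["utilities.u_post_year1"].base,
        u_post_later=inputs["utilities.u_post_later"].base,
    )
    mortality = MortalityParams(
        cancer_annual_mortality=inputs["mortality.cancer_annual_mortality"].base,
        fn_case_fatality=inputs["mortality.fn_case_fatality"].base,
        hr_low_rdi=inputs["mortality.hr_low_rdi"].base,
    )
    scaffold = datasets.cost_scaffold()
    costs = CostParams(
        agent=agent,
        drug_unit_price=_FILGRASTIM_LIST_PRICE if agent == "filgrastim" else 430.75,
        fn_hospitalisation_cost=4000.0,
        **scaffold,
    )
    provenance = {f"clinical.{f.name}": "published"
                  for f in dataclasses.fields(ClinicalParams)}
    provenance.update({f"utilities.{f.name}": "published"
                       for f in dataclasses.fields(UtilityParams)})
    provenance.update({f"mortality.{f.name}": "published"
                       for f in dataclasses.fields(MortalityParams)})
    provenance.update({
        "cohort.entry_age": "fixture", "cohort.sex_mix": "fixture",
        "life_table": "fixture", "discount_rate_costs": "fixture",
        "discount_rate_effects": "fixture",
        "costs.los_days": "fixture", "costs.patient_weight_kg": "fixture",
        "costs.doses_per_cycle": "fixture",
        "costs.drug_unit_price": "fixture",
        "costs.fn_hospitalisation_cost": "fixture",
    })
    cfg = ScenarioConfig(
        scenario_id=datasets.fixture_id(country, cancer, agent),
        country=country,
        cohort=cohort,
        clinical=clinical,
        utilities=utilities,
        mortality=mortality,
        costs=costs,
        life_table=cset["gompertz"],
        discount_rate_costs=cset["discount_rate"],
        discount_rate_effects=cset["discount_rate"],
        provenance=tuple(provenance.items()),
    )
    if calibrate:
        target = CalibrationTarget.from_published(country, cancer, agent)
        costs = calibrate_costs(target, cfg)
        provenance["costs.drug_unit_price"] = "calibrated"
        provenance["costs.fn_hospitalisation_cost"] = "calibrated"
        cfg = dataclasses.replace(cfg, costs=costs,
                                  provenance=tuple(provenance.items()))
    cfg = dataclasses.replace(
        cfg,
        uncertainty=_uncertainty_for(cancer, agent, cfg.costs,
                                     cset["discount_rate"]),
    )
    return cfg


def build_fixtures(out_dir=None) -> pd.DataFrame:
    """Build all 18 calibrated scenarios; optionally write fixture files.

    Returns the calibration report: solved costs, their provenance, and a
    sanity flag comparing the solved filgrastim per-cycle cost with the
    published list price (expected within 1x-20x of EUR 55.54)."""
    rows = []
    for country in datasets.COUNTRIES:
        for cancer in datasets.CANCERS:
            for agent in datasets.AGENTS:
                try:
                    cfg = build_scenario(country, cancer, agent, calibrate=True)
                except CalibrationError as exc:
                    raise CalibrationError(
                        f"fixture {country}/{cancer}/{agent} failed: {exc}"
                    ) from exc
                per_cycle = cfg.costs.cycle_drug_cost()
                flag = ""
                if agent == "filgrastim":
                    lo = _SANITY_BAND[0] * _FILGRASTIM_LIST_PRICE
                    hi = _SANITY_BAND[1] * _FILGRASTIM_LIST_PRICE
                    if not (lo <= per_cycle <= hi):
                        flag = "outside list-price sanity band"
                rows.append(dict(
                    scenario_id=cfg.scenario_id, country=country, cancer=cancer,
                    agent=agent,
                    gcsf_cost_per_cycle=per_cycle,
                    drug_unit_price=cfg.costs.drug_unit_price,
                    fn_hospitalisation_cost=cfg.costs.fn_hospitalisation_cost,
                    provenance="calibrated", flag=flag,
                ))
                if out_dir is not None:
                    out_dir = Path(out_dir)
                    out_dir.mkdir(parents=True, exist_ok=True)
                    save_scenario(cfg, out_dir / f"{cfg.scenario_id}.json")
    report = pd.DataFrame(rows)
    if out_dir is not None:
        report.to_csv(Path(out_dir) / "calibration_report.csv", index=False)
    return report
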