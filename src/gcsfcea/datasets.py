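"""Reference inputs and results of the original published European analysis.

This package re-implements a published decision-tree/Markov cohort
cost-effectiveness model of primary (PP) versus secondary (SP) G-CSF
prophylaxis of febrile neutropenia (FN) in breast cancer (BC), non-small
cell lung cancer (NSCLC) and non-Hodgkin's lymphoma (NHL) for Austria,
France and Germany.  This module holds, as data:

* the published clinical/utility/mortality inputs with their PSA ranges
  and distribution families (one table, cancer-specific where published);
* the published base-case results (costs, FN events avoided, LYs, QALYs
  and ICERs per strategy) used to calibrate the unpublished cost inputs
  and to verify the incremental arithmetic;
* fixture-level settings this package chooses where the original analysis
  did not publish them (entry ages, sex mixes, discount rates, synthetic
  national life tables, dosing scaffold) — marked provenance "fixture".
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .lifetables import GompertzLifeTableSpec
from .params import UncertainParameter

__all__ = [
    "CANCERS",
    "COUNTRIES",
    "AGENTS",
    "clinical_inputs",
    "base_case_results",
    "base_case_row",
    "printed_icers",
    "country_settings",
    "cohort_profile_inputs",
    "cost_scaffold",
    "fixture_id",
    "fixture_path",
    "fixture_ids",
]

CANCERS = ("BC", "NSCLC", "NHL")
COUNTRIES = ("Austria", "France", "Germany")
AGENTS = ("filgrastim", "pegfilgrastim")


# --------------------------------------------------------------------------
# Published clinical table: base (low-high), distribution family.
# Keys are config field paths so sensitivity analyses can apply them back.

_SHARED_CLINICAL = {
    "clinical.rr_later_cycles": (0.21, 0.16, 0.29, "lognormal"),
    "clinical.rr_history": (9.09, 6.19, 13.35, "lognormal"),
    "utilities.u_fn_hosp": (0.33, 0.27, 0.40, "beta"),
}

_BY_CANCER = {
    "BC": {
        "clinical.baseline_fn_risk": (0.158, 0.100, 0.200, "beta"),
        "clinical.p_low_rdi_no_fn": (0.309, 0.278, 0.340, "beta"),
        "clinical.p_low_rdi_fn": (0.488, 0.371, 0.649, "beta"),
        "utilities.u_chemo": (0.55, 0.50, 0.61, "beta"),
        "utilities.u_post_year1": (0.66, 0.59, 0.73, "beta"),
        "utilities.u_post_later": (0.86, 0.77, 0.95, "beta"),
        "mortality.cancer_annual_mortality": (0.0300, 0.0270, 0.0330, "beta"),
        "mortality.fn_case_fatality": (0.0560, 0.0480, 0.0630, "beta"),
        "mortality.hr_low_rdi": (1.002, 0.657, 1.527, "lognormal"),
    },
    "NSCLC": {
        "clinical.baseline_fn_risk": (0.180, 0.100, 0.200, "beta"),
        "clinical.p_low_rdi_no_fn": (0.250, 0.225, 0.275, "beta"),
        "clinical.p_low_rdi_fn": (0.383, 0.345, 0.421, "beta"),
        "utilities.u_chemo": (0.57, 0.51, 0.63, "beta"),
        "utilities.u_post_year1": (0.72, 0.65, 0.79, "beta"),
        "utilities.u_post_later": (0.69, 0.62, 0.76, "beta"),
        "mortality.cancer_annual_mortality": (0.0600, 0.0540, 0.0660, "beta"),
        "mortality.fn_case_fatality": (0.1120, 0.1010, 0.1230, "beta"),
        "mortality.hr_low_rdi": (2.004, 1.159, 3.463, "lognormal"),
    },
    "NHL": {
        "clinical.baseline_fn_risk": (0.180, 0.100, 0.200, "beta"),
        "clinical.p_low_rdi_no_fn": (0.408, 0.367, 0.449, "beta"),
        "clinical.p_low_rdi_fn": (0.706, 0.635, 0.777, "beta"),
        "utilities.u_chemo": (0.61, 0.49, 0.73, "beta"),
        "utilities.u_post_year1": (0.79, 0.62, 0.92, "beta"),
        "utilities.u_post_later": (0.89, 0.79, 0.96, "beta"),
        "mortality.cancer_annual_mortality": (0.0652, 0.0587, 0.0717, "beta"),
        "mortality.fn_case_fatality": (0.0580, 0.0000, 0.0890, "beta"),
        "mortality.hr_low_rdi": (2.080, 1.190, 3.700, "lognormal"),
    },
}

# RR of FN on prophylaxis vs none.  Filgrastim's range was published; the
# pegfilgrastim point estimate was published without a range, so its fixture
# range carries over the filgrastim log-scale uncertainty.
_RR_GCSF = {
    "filgrastim": (0.42, 0.30, 0.57, "lognormal"),
    "pegfilgrastim": (0.25, 0.25 * 0.30 / 0.42, 0.25 * 0.57 / 0.42, "lognormal"),
}

# RDI threshold (percent) below which the mortality hazard ratio applies.
RDI_THRESHOLD_PCT = {"BC": 85.0, "NSCLC": 85.0, "NHL": 90.0}


def clinical_inputs(cancer: str, agent: str) -> dict[str, UncertainParameter]:
    """Published inputs for one cancer/agent as UncertainParameters keyed by
    config field path."""
    rows = {**_SHARED_CLINICAL, **_BY_CANCER[cancer],
            "clinical.rr_gcsf": _RR_GCSF[agent]}
    return {
        name: UncertainParameter(name=name, base=b, low=lo, high=hi, family=fam)
        for name, (b, lo, hi, fam) in rows.items()
    }


# --------------------------------------------------------------------------
# Published base-case results.  Per (country, cancer, agent, strategy):
# total discounted cost (EUR), FN events avoided (vs no prophylaxis),
# life years, QALYs.  ICERs as printed; "Dominates" where PP was both
# cheaper and more effective.

_BASE_CASE = {
    # country, cancer, agent: (PP row, SP row, (icer_fn, icer_ly, icer_qaly))
    ("Austria", "BC", "filgrastim"): (
        (1567, 0.135, 13.024, 10.997), (980, 0.035, 12.951, 10.934),
        (5840, 8029, 9219)),
    ("Austria", "NSCLC", "filgrastim"): (
        (1847, 0.156, 8.743, 6.023), (1736, 0.041, 8.597, 5.919),
        (972, 758, 1069)),
    ("Austria", "NHL", "filgrastim"): (
        (2506, 0.172, 8.348, 7.266), (1862, 0.054, 8.194, 7.127),
        (5459, 4195, 4646)),
    ("Austria", "BC", "pegfilgrastim"): (
        (1787, 0.168, 13.099, 11.063), (959, 0.045, 13.009, 10.984),
        (6724, 9205, 10568)),
    ("Austria", "NSCLC", "pegfilgrastim"): (
        (1957, 0.194, 8.791, 6.057), (1672, 0.054, 8.608, 5.927),
        (2036, 1558, 2199)),
    ("Austria", "NHL", "pegfilgrastim"): (
        (2751, 0.212, 8.397, 7.310), (1786, 0.070, 8.201, 7.133),
        (6781, 4926, 5458)),
    ("France", "BC", "filgrastim"): (
        (1880, 0.135, 12.943, 10.928), (1430, 0.035, 12.870, 10.865),
        (4489, 6211, 7131)),
    ("France", "NSCLC", "filgrastim"): (
        (2323, 0.156, 8.272, 5.697), (2475, 0.041, 8.134, 5.599),
        ("Dominates", "Dominates", "Dominates")),
    ("France", "NHL", "filgrastim"): (
        (3165, 0.172, 7.974, 6.933), (2407, 0.054, 7.829, 6.802),
        (6421, 5248, 5807)),
    ("France", "BC", "pegfilgrastim"): (
        (2406, 0.168, 13.014, 10.990), (1416, 0.045, 12.925, 10.912),
        (8039, 11076, 12715)),
    ("France", "NSCLC", "pegfilgrastim"): (
        (2656, 0.194, 8.316, 5.729), (2398, 0.054, 8.144, 5.607),
        (1839, 1499, 2112)),
    ("France", "NHL", "pegfilgrastim"): (
        (3656, 0.212, 8.020, 6.974), (2325, 0.070, 7.836, 6.808),
        (9358, 7233, 8008)),
    ("Germany", "BC", "filgrastim"): (
        (2411, 0.135, 13.812, 11.675), (525, 0.035, 13.734, 11.608),
        (18781, 24334, 27960)),
    ("Germany", "NSCLC", "filgrastim"): (
        (2554, 0.156, 8.650, 5.959), (1003, 0.041, 8.505, 5.856),
        (13550, 10698, 15090)),
    ("Germany", "NHL", "filgrastim"): (
        (3904, 0.172, 8.397, 7.310), (1437, 0.054, 8.242, 7.169),
        (20909, 15878, 17588)),
    ("Germany", "BC", "pegfilgrastim"): (
        (4077, 0.168, 13.889, 11.742), (646, 0.045, 13.794, 11.659),
        (27862, 35951, 41305)),
    ("Germany", "NSCLC", "pegfilgrastim"): (
        (4181, 0.194, 8.697, 5.992), (1108, 0.054, 8.517, 5.864),
        (21932, 17003, 23990)),
    ("Germany", "NHL", "pegfilgrastim"): (
        (6252, 0.212, 8.447, 7.354), (1594, 0.070, 8.248, 7.175),
        (32746, 23499, 26046)),
}


def base_case_results() -> pd.DataFrame:
    """All published base-case rows as a tidy table."""
    rows = []
    for (country, cancer, agent), (pp, sp, _) in _BASE_CASE.items():
        for strategy, vals in (("PP", pp), ("SP", sp)):
            rows.append(
                dict(country=country, cancer=cancer, agent=agent, strategy=strategy,
                     cost=float(vals[0]), fn_events_avoided=vals[1],
                     ly=vals[2], qaly=vals[3])
            )
    return pd.DataFrame(rows)


def base_case_row(country: str, cancer: str, agent: str, strategy: str) -> dict:
    pp, sp, _ = _BASE_CASE[(country, cancer, agent)]
    vals = pp if strategy == "PP" else sp
    return dict(cost=float(vals[0]), fn_events_avoided=vals[1], ly=vals[2], qaly=vals[3])


def printed_icers(country: str, cancer: str, agent: str) -> tuple:
    """Published (ICER per FN avoided, per LY, per QALY); 'Dominates' markers
    where PP was cheaper and more effective."""
    return _BASE_CASE[(country, cancer, agent)][2]


# --------------------------------------------------------------------------
# Fixture-level settings chosen by this package (provenance "fixture").

# Discount rates follow national HTA conventions; synthetic Gompertz life
# tables stand in for national period life tables.
_COUNTRY = {
    "Austria": dict(
        discount_rate=0.05,
        gompertz=GompertzLifeTableSpec(a=2.4e-5, b=0.095, terminal_age=110,
                                       male_factor=1.7),
    ),
    "France": dict(
        discount_rate=0.025,
        gompertz=GompertzLifeTableSpec(a=2.1e-5, b=0.095, terminal_age=110,
                                       male_factor=1.9),
    ),
    "Germany": dict(
        discount_rate=0.03,
        gompertz=GompertzLifeTableSpec(a=2.5e-5, b=0.095, terminal_age=110,
                                       male_factor=1.6),
    ),
}

# Entry age and sex mix per cancer follow the predecessor US model's cohort
# choices (not republished in the European analysis).
_COHORT = {
    "BC": dict(entry_age=50.0, sex_mix=1.00),
    "NSCLC": dict(entry_age=65.0, sex_mix=0.35),
    "NHL": dict(entry_age=62.0, sex_mix=0.45),
}

# Dosing/LOS scaffold (the published supplementary cost table is not
# available): daily filgrastim for 5 days per cycle, 70 kg reference
# patient, 8-day FN admission.  OWSA ranges below are fixture choices.
COST_SCAFFOLD = dict(patient_weight_kg=70.0, doses_per_cycle=5, los_days=8.0)
COST_OWSA_FRACTION = 0.20  # +/- range applied to calibrated cost inputs
LOS_RANGE = (5.0, 11.0)
WEIGHT_RANGE = (60.0, 90.0)
DISCOUNT_RANGE = (0.0, 0.05)


def country_settings(country: str) -> dict:
    return _COUNTRY[country]


def cohort_profile_inputs(cancer: str) -> dict:
    return dict(_COHORT[cancer])


def cost_scaffold() -> dict:
    return dict(COST_SCAFFOLD)


# --------------------------------------------------------------------------
# Bundled fixtures

def fixture_id(country: str, cancer: str, agent: str) -> str:
    return f"{country.lower()}_{cancer.lower()}_{agent}"


def fixture_ids() -> list[str]:
    return [fixture_id(co, ca, ag)
            for co in COUNTRIES for ca in CANCERS for ag in AGENTS]


def fixture_path(scenario_id: str):
    """Path to a bundled scenario fixture by id (e.g. austria_bc_filgrastim)."""
    return resources.files("gcsfcea.data.fixtures").joinpath(f"{scenario_id}.json")
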