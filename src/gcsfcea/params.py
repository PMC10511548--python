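"""Typed model parameters, scenario configuration I/O, and PSA distributions.

A scenario bundles everything one cancer x country x agent case needs:
cohort profile, clinical risks, utilities, mortality, costs, discounting,
a life-table reference, and the list of uncertain parameters with their
probabilistic-sensitivity-analysis (PSA) ranges.

Ranges are read as 95% intervals.  Beta distributions are fitted by moment
matching (mean = base, sd = (high - low)/3.92); lognormals take
log-mean = ln(base) and log-sd = (ln(high) - ln(low))/3.92.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .errors import ConfigurationError, ValidationError
from .lifetables import GompertzLifeTableSpec, LifeTable

__all__ = [
    "CohortProfile",
    "ClinicalParams",
    "UtilityParams",
    "MortalityParams",
    "CostParams",
    "UncertainParameter",
    "ScenarioConfig",
    "fit_distribution",
    "sample_parameter",
    "load_scenario",
    "save_scenario",
    "scenario_from_dict",
    "scenario_to_dict",
]

CANCERS = ("BC", "NSCLC", "NHL")
AGENTS = ("filgrastim", "pegfilgrastim")
STRATEGIES = ("PP", "SP")

# filgrastim dosing: 5 ug/kg/day rounded up to whole 300 ug vials
_FILGRASTIM_DOSE_UG_PER_KG = 5.0
_FILGRASTIM_VIAL_UG = 300.0


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


def _prob(value: float, name: str) -> None:
    _check(0.0 <= value <= 1.0, f"{name}: must lie in [0, 1], got {value}")


@dataclass(frozen=True)
class CohortProfile:
    """Who enters the model: cancer type, demographics, and cycle structure."""

    cancer: str
    entry_age: float
    sex_mix: float  # proportion female
    n_cycles: int = 6
    cycle_length_days: float = 21.0
    cure_horizon_years: int = 20

    def __post_init__(self) -> None:
        _check(self.cancer in CANCERS, f"cancer: must be one of {CANCERS}, got {self.cancer!r}")
        _check(self.entry_age > 0, f"entry_age: must be > 0, got {self.entry_age}")
        _prob(self.sex_mix, "sex_mix")
        _check(self.n_cycles >= 1, f"n_cycles: must be >= 1, got {self.n_cycles}")
        _check(
            self.cycle_length_days > 0,
            f"cycle_length_days: must be > 0, got {self.cycle_length_days}",
        )
        _check(
            self.cure_horizon_years >= 0,
            f"cure_horizon_years: must be >= 0, got {self.cure_horizon_years}",
        )


@dataclass(frozen=True)
class ClinicalParams:
    """Febrile-neutropenia (FN) risk structure for one cancer and agent.

    ``baseline_fn_risk`` is the probability of at least one FN event over
    the whole chemotherapy course for a patient without prophylaxis.
    Relative risks modify the per-cycle probability: later cycles carry a
    lower risk than cycle 1 (``rr_later_cycles``), a prior FN event raises
    it (``rr_history``), and G-CSF prophylaxis lowers it (``rr_gcsf``).
    """

    baseline_fn_risk: float
    rr_later_cycles: float
    rr_history: float
    rr_gcsf: float
    p_low_rdi_no_fn: float
    p_low_rdi_fn: float
    rdi_threshold_pct: float = 85.0

    def __post_init__(self) -> None:
        _prob(self.baseline_fn_risk, "baseline_fn_risk")
        _check(self.rr_later_cycles > 0, f"rr_later_cycles: must be > 0, got {self.rr_later_cycles}")
        _check(self.rr_history > 0, f"rr_history: must be > 0, got {self.rr_history}")
        _check(0 < self.rr_gcsf < 1, f"rr_gcsf: must lie in (0, 1), got {self.rr_gcsf}")
        _prob(self.p_low_rdi_no_fn, "p_low_rdi_no_fn")
        _prob(self.p_low_rdi_fn, "p_low_rdi_fn")
        _check(
            self.rdi_threshold_pct > 0,
            f"rdi_threshold_pct: must be > 0, got {self.rdi_threshold_pct}",
        )


@dataclass(frozen=True)
class UtilityParams:
    """Health-state utilities (per year of life, each in [0, 1])."""

    u_chemo: float
    u_fn_hosp: float
    u_post_year1: float
    u_post_later: float

    def __post_init__(self) -> None:
        for name in ("u_chemo", "u_fn_hosp", "u_post_year1", "u_post_later"):
            _prob(getattr(self, name), name)
        _check(
            self.u_fn_hosp <= self.u_chemo,
            f"u_fn_hosp: must be <= u_chemo ({self.u_chemo}), got {self.u_fn_hosp}",
        )


@dataclass(frozen=True)
class MortalityParams:
    """Excess mortality: cancer-related annual risk, FN case fatality, and
    the hazard ratio carried by a low relative dose intensity (RDI)."""

    cancer_annual_mortality: float
    fn_case_fatality: float
    hr_low_rdi: float

    def __post_init__(self) -> None:
        _prob(self.cancer_annual_mortality, "cancer_annual_mortality")
        _prob(self.fn_case_fatality, "fn_case_fatality")
        _check(self.hr_low_rdi > 0, f"hr_low_rdi: must be > 0, got {self.hr_low_rdi}")


@dataclass(frozen=True)
class CostParams:
    """Cost inputs (euros) and the dosing rule that links drug price to a
    per-cycle prophylaxis cost.

    Filgrastim is dosed daily at 5 ug/kg rounded up to whole 300 ug vials,
    so the patient's weight drives the number of vials per dose;
    pegfilgrastim is one dose per cycle.  ``gcsf_cost_per_cycle`` may be
    given directly, overriding the price x dosing derivation.
    """

    agent: str
    drug_unit_price: float
    fn_hospitalisation_cost: float
    los_days: float
    patient_weight_kg: float = 70.0
    doses_per_cycle: int = 5
    gcsf_cost_per_cycle: Optional[float] = None

    def __post_init__(self) -> None:
        _check(self.agent in AGENTS, f"agent: must be one of {AGENTS}, got {self.agent!r}")
        for name in ("drug_unit_price", "fn_hospitalisation_cost", "los_days",
                     "patient_weight_kg"):
            _check(getattr(self, name) >= 0, f"{name}: must be >= 0, got {getattr(self, name)}")
        _check(
            1 <= self.doses_per_cycle <= 14,
            f"doses_per_cycle: must lie in [1, 14], got {self.doses_per_cycle}",
        )
        if self.gcsf_cost_per_cycle is not None:
            _check(
                self.gcsf_cost_per_cycle >= 0,
                f"gcsf_cost_per_cycle: must be >= 0, got {self.gcsf_cost_per_cycle}",
            )

    @property
    def units_per_dose(self) -> int:
        if self.agent == "pegfilgrastim":
            return 1
        return int(
            math.ceil(
                _FILGRASTIM_DOSE_UG_PER_KG * self.patient_weight_kg / _FILGRASTIM_VIAL_UG
            )
        )

    @property
    def effective_doses_per_cycle(self) -> int:
        return 1 if self.agent == "pegfilgrastim" else self.doses_per_cycle

    def cycle_drug_cost(self) -> float:
        """Prophylaxis drug cost per chemotherapy cycle."""
        if self.gcsf_cost_per_cycle is not None:
            return self.gcsf_cost_per_cycle
        return self.drug_unit_price * self.units_per_dose * self.effective_doses_per_cycle


@dataclass(frozen=True)
class UncertainParameter:
    """One model input with its base value, 95% range, and PSA family."""

    name: str
    base: float
    low: float
    high: float
    family: str  # beta | lognormal | fixed
    hyper: Optional[tuple] = None

    def __post_init__(self) -> None:
        _check(
            self.family in ("beta", "lognormal", "fixed"),
            f"family: must be beta/lognormal/fixed, got {self.family!r}",
        )
        _check(
            self.low <= self.base <= self.high,
            f"{self.name}: need low <= base <= high, got ({self.low}, {self.base}, {self.high})",
        )
        if self.hyper is not None:
            object.__setattr__(self, "hyper", tuple(float(h) for h in self.hyper))


def fit_distribution(p: UncertainParameter) -> UncertainParameter:
    """Populate ``hyper`` from (base, low, high) for the parameter's family.

    beta:      moment matching — mean = base, sd = (high - low)/3.92
    lognormal: log-mean = ln(base), log-sd = (ln(high) - ln(low))/3.92
    fixed:     degenerate at base
    """
    if p.family == "fixed":
        return dataclasses.replace(p, hyper=(p.base,))
    if p.family == "beta":
        if not 0.0 < p.base < 1.0:
            raise ValidationError(
                f"{p.name}: beta requires base in (0, 1), got {p.base}"
            )
        if not (0.0 <= p.low and p.high <= 1.0):
            raise ValidationError(
                f"{p.name}: beta requires support within [0, 1], got ({p.low}, {p.high})"
            )
        mean = p.base
        sd = (p.high - p.low) / 3.92
        if sd <= 0.0:
            return dataclasses.replace(p, family="fixed", hyper=(p.base,))
        nu = mean * (1.0 - mean) / sd**2 - 1.0
        if nu <= 0.0:
            raise ValidationError(
                f"{p.name}: beta moment matching failed (variance too large for mean {mean})"
            )
        return dataclasses.replace(p, hyper=(mean * nu, (1.0 - mean) * nu))
    # lognormal
    if not (p.low > 0 and p.base > 0 and p.high > 0):
        raise ValidationError(
            f"{p.name}: lognormal requires positive bounds, got ({p.low}, {p.base}, {p.high})"
        )
    mu = math.log(p.base)
    sigma = (math.log(p.high) - math.log(p.low)) / 3.92
    if sigma == 0.0:
        return dataclasses.replace(p, family="fixed", hyper=(p.base,))
    return dataclasses.replace(p, hyper=(mu, sigma))


def sample_parameter(p: UncertainParameter, rng: np.random.Generator, size=None):
    """Draw from a fitted parameter's distribution."""
    if p.hyper is None:
        p = fit_distribution(p)
    if p.family == "fixed":
        return np.full(size, p.hyper[0]) if size is not None else p.hyper[0]
    if p.family == "beta":
        return rng.beta(p.hyper[0], p.hyper[1], size=size)
    return rng.lognormal(p.hyper[0], p.hyper[1], size=size)


@dataclass(frozen=True)
class ScenarioConfig:
    """One fully specified cancer x country x agent case."""

    scenario_id: str
    country: str
    cohort: CohortProfile
    clinical: ClinicalParams
    utilities: UtilityParams
    mortality: MortalityParams
    costs: CostParams
    life_table: object  # GompertzLifeTableSpec | path str | LifeTable
    discount_rate_costs: float = 0.03
    discount_rate_effects: float = 0.03
    wtp_grid: tuple = tuple(range(0, 105_000, 5_000))
    psa_iterations: int = 1000
    seed: int = 20230
    uncertainty: tuple = ()
    provenance: tuple = ()  # ((field, paper|fixture|calibrated|user), ...)
    half_cycle: str = "mid"  # mid | none
    rr_scale: str = "probability"  # probability | rate

    def __post_init__(self) -> None:
        for name in ("discount_rate_costs", "discount_rate_effects"):
            v = getattr(self, name)
            _check(0.0 <= v <= 0.2, f"{name}: must lie in [0, 0.2], got {v}")
        _check(
            self.psa_iterations >= 1,
            f"psa_iterations: must be >= 1, got {self.psa_iterations}",
        )
        grid = tuple(float(w) for w in self.wtp_grid)
        object.__setattr__(self, "wtp_grid", grid)
        _check(
            all(b > a for a, b in zip(grid, grid[1:])),
            "wtp_grid: must be strictly increasing",
        )
        _check(self.half_cycle in ("mid", "none"),
               f"half_cycle: must be 'mid' or 'none', got {self.half_cycle!r}")
        _check(self.rr_scale in ("probability", "rate"),
               f"rr_scale: must be 'probability' or 'rate', got {self.rr_scale!r}")
        _check(
            self.costs.los_days <= self.cohort.cycle_length_days,
            f"los_days: must be <= cycle_length_days ({self.cohort.cycle_length_days}), "
            f"got {self.costs.los_days}",
        )
        object.__setattr__(self, "uncertainty", tuple(self.uncertainty))
        object.__setattr__(
            self, "provenance", tuple((str(k), str(v)) for k, v in self.provenance)
        )

    def provenance_of(self, field_name: str) -> str:
        for k, v in self.provenance:
            if k == field_name:
                return v
        return "user"


# ---------------------------------------------------------------------------
# serialization

_REQUIRED_TOP = ("scenario_id", "country", "cohort", "clinical", "utilities",
                 "mortality", "costs", "life_table")


def _require(mapping: dict, key: str, where: str):
    if key not in mapping:
        raise ConfigurationError(f"missing required key {key!r} in {where}")
    return mapping[key]


def _build(cls, mapping: dict, where: str):
    names = [f.name for f in dataclasses.fields(cls)]
    required = {
        f.name
        for f in dataclasses.fields(cls)
        if f.default is dataclasses.MISSING and f.default_factory is dataclasses.MISSING
    }
    unknown = set(mapping) - set(names)
    if unknown:
        raise ConfigurationError(f"unknown keys {sorted(unknown)} in {where}")
    for key in required:
        _require(mapping, key, where)
    return cls(**mapping)


def scenario_from_dict(raw: dict) -> ScenarioConfig:
    """Validate a plain mapping (parsed JSON/YAML) into a ScenarioConfig."""
    if not isinstance(raw, dict):
        raise ConfigurationError("scenario file must parse to a mapping")
    for key in _REQUIRED_TOP:
        _require(raw, key, "scenario")
    lt = raw["life_table"]
    if isinstance(lt, dict):
        if "gompertz" in lt:
            life_table = _build(GompertzLifeTableSpec, lt["gompertz"], "life_table.gompertz")
        elif "csv" in lt:
            life_table = str(lt["csv"])
        else:
            raise ConfigurationError("life_table: expected 'gompertz' or 'csv' key")
    elif isinstance(lt, str):
        life_table = lt
    else:
        raise ConfigurationError("life_table: expected mapping or path string")
    unc = tuple(
        _build(UncertainParameter, u, f"uncertainty[{i}]")
        for i, u in enumerate(raw.get("uncertainty", []))
    )
    prov = tuple((k, v) for k, v in dict(raw.get("provenance", {})).items())
    extra = {
        k: raw[k]
        for k in ("discount_rate_costs", "discount_rate_effects", "wtp_grid",
                  "psa_iterations", "seed", "half_cycle", "rr_scale")
        if k in raw
    }
    if "wtp_grid" in extra:
        extra["wtp_grid"] = tuple(extra["wtp_grid"])
    return ScenarioConfig(
        scenario_id=str(raw["scenario_id"]),
        country=str(raw["country"]),
        cohort=_build(CohortProfile, raw["cohort"], "cohort"),
        clinical=_build(ClinicalParams, raw["clinical"], "clinical"),
        utilities=_build(UtilityParams, raw["utilities"], "utilities"),
        mortality=_build(MortalityParams, raw["mortality"], "mortality"),
        costs=_build(CostParams, raw["costs"], "costs"),
        life_table=life_table,
        uncertainty=unc,
        provenance=prov,
        **extra,
    )


def scenario_to_dict(cfg: ScenarioConfig) -> dict:
    def plain(obj):
        d = dataclasses.asdict(obj)
        return {k: v for k, v in d.items() if v is not None}

    if isinstance(cfg.life_table, GompertzLifeTableSpec):
        lt = {"gompertz": plain(cfg.life_table)}
    elif isinstance(cfg.life_table, LifeTable):
        raise ConfigurationError(
            "cannot serialize an in-memory LifeTable; use a Gompertz spec or CSV path"
        )
    else:
        lt = {"csv": str(cfg.life_table)}
    out = {
        "scenario_id": cfg.scenario_id,
        "country": cfg.country,
        "cohort": plain(cfg.cohort),
        "clinical": plain(cfg.clinical),
        "utilities": plain(cfg.utilities),
        "mortality": plain(cfg.mortality),
        "costs": plain(cfg.costs),
        "life_table": lt,
        "discount_rate_costs": cfg.discount_rate_costs,
        "discount_rate_effects": cfg.discount_rate_effects,
        "wtp_grid": list(cfg.wtp_grid),
        "psa_iterations": cfg.psa_iterations,
        "seed": cfg.seed,
        "half_cycle": cfg.half_cycle,
        "rr_scale": cfg.rr_scale,
        "uncertainty": [
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in plain(u).items()}
            for u in cfg.uncertainty
        ],
        "provenance": dict(cfg.provenance),
    }
    return out


def load_scenario(path) -> ScenarioConfig:
    """Load and validate a scenario file (JSON or YAML)."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"scenario file not found: {path}")
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    return scenario_from_dict(raw)


def save_scenario(cfg: ScenarioConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(scenario_to_dict(cfg), fh, indent=1, sort_keys=True)
        fh.write("\n")
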