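"""One-way (tornado) and probabilistic sensitivity analyses.

The OWSA reruns the full base case at each parameter's low and high bound
holding everything else at base, and ranks parameters by the swing they
induce on the cost-per-QALY scale (dominance outcomes map to 0 on that
scale for ordering).  The PSA draws all uncertain parameters jointly and
independently from their fitted distributions — one value per parameter
per iteration, shared between the PP and SP arms — and evaluates the full
model per draw.  Random numbers come from per-(iteration, parameter)
counter-derived substreams, so results do not depend on parameter
evaluation order and are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cea import ceac, incremental, DOMINANT, DOMINATED
from .cohort import run_strategy
from .errors import ValidationError
from .lifetables import resolve_life_table
from .params import ScenarioConfig, UncertainParameter, fit_distribution, sample_parameter
from .risk import build_risk_table

__all__ = ["TornadoEntry", "PsaResult", "owsa", "psa", "apply_parameter"]

log = logging.getLogger(__name__)


def apply_parameter(cfg: ScenarioConfig, name: str, value: float) -> ScenarioConfig:
    """Return a copy of ``cfg`` with one dotted-path field replaced.

    The alias ``discount_rate`` sets both the cost and effect rates.
    """
    if name == "discount_rate":
        return dataclasses.replace(
            cfg, discount_rate_costs=value, discount_rate_effects=value
        )
    if "." in name:
        section, fieldname = name.split(".", 1)
        sub = getattr(cfg, section, None)
        if sub is None or not dataclasses.is_dataclass(sub):
            raise ValidationError(f"unknown parameter section {section!r} in {name!r}")
        if fieldname not in {f.name for f in dataclasses.fields(sub)}:
            raise ValidationError(f"unknown parameter field {name!r}")
        if fieldname == "doses_per_cycle":
            value = int(round(value))
        return dataclasses.replace(cfg, **{section: dataclasses.replace(sub, **{fieldname: value})})
    if name not in {f.name for f in dataclasses.fields(cfg)}:
        raise ValidationError(f"unknown parameter {name!r}")
    return dataclasses.replace(cfg, **{name: value})


def _icer_qaly_value(cfg: ScenarioConfig):
    pp = run_strategy(cfg, "PP")
    sp = run_strategy(cfg, "SP")
    res = incremental(pp, sp)
    if res.status == "icer" and isinstance(res.icer_qaly, float):
        return res.icer_qaly, res.status
    return None, res.status


def _swing_scale(icer) -> float:
    # dominance / markers map to 0 on the cost-per-QALY scale for ordering
    return icer if isinstance(icer, float) else 0.0


@dataclass(frozen=True)
class TornadoEntry:
    """One OWSA row: the base-case ICER recomputed at a parameter's bounds."""

    name: str
    icer_at_low: object  # EUR/QALY, or a dominance/status marker string
    icer_at_high: object
    status_at_low: str
    status_at_high: str
    swing: float

    def __post_init__(self) -> None:
        if self.swing < 0:
            raise ValidationError(f"swing: must be >= 0, got {self.swing}")


def owsa(
    cfg: ScenarioConfig,
    params: Optional[Sequence[UncertainParameter]] = None,
) -> list[TornadoEntry]:
    """One-way sensitivity analysis over the scenario's uncertain inputs.

    Parameters whose bounds violate a structural invariant (for example a
    utility above 1) are skipped with a logged warning.  Entries are
    sorted by descending swing on the cost-per-QALY scale.
    """
    if params is None:
        params = cfg.uncertainty
    entries = []
    for p in params:
        icers = []
        statuses = []
        try:
            for bound in (p.low, p.high):
                cfg_b = apply_parameter(cfg, p.name, bound)
                icer, status = _icer_qaly_value(cfg_b)
                icers.append(icer if icer is not None else status)
                statuses.append(status)
        except ValidationError as exc:
            log.warning("OWSA: skipping %s (%s)", p.name, exc)
            continue
        swing = abs(_swing_scale(icers[1]) - _swing_scale(icers[0]))
        entries.append(
            TornadoEntry(
                name=p.name,
                icer_at_low=icers[0],
                icer_at_high=icers[1],
                status_at_low=statuses[0],
                status_at_high=statuses[1],
                swing=swing,
            )
        )
    entries.sort(key=lambda e: (-e.swing, e.name))
    return entries


@dataclass(frozen=True)
class PsaResult:
    """Paired per-iteration PSA draws for PP and SP plus the CEAC."""

    seed: int
    n: int
    wtp_grid: tuple
    pp_cost: np.ndarray
    pp_ly: np.ndarray
    pp_qaly: np.ndarray
    pp_fn_events: np.ndarray
    sp_cost: np.ndarray
    sp_ly: np.ndarray
    sp_qaly: np.ndarray
    sp_fn_events: np.ndarray
    ceac: np.ndarray
    n_clamped: int = 0
    drawn: dict = field(default_factory=dict)

    def ceac_at(self, wtp: float) -> float:
        grid = np.asarray(self.wtp_grid, dtype=float)
        idx = int(np.argmin(np.abs(grid - wtp)))
        if grid[idx] != wtp:
            raise ValidationError(f"wtp {wtp} not on the configured grid")
        return float(self.ceac[idx])


# probability-like fields clamped to [0,1]; structural pairs restored below
_CLAMP_UNIT = {
    "clinical.baseline_fn_risk", "clinical.p_low_rdi_no_fn", "clinical.p_low_rdi_fn",
    "utilities.u_chemo", "utilities.u_fn_hosp", "utilities.u_post_year1",
    "utilities.u_post_later", "mortality.cancer_annual_mortality",
    "mortality.fn_case_fatality",
}


def _clamp_draws(draws: dict, cfg: ScenarioConfig) -> tuple[dict, bool]:
    """Apply the documented clamping/ordering rules to one joint draw."""
    clamped = False
    out = dict(draws)
    for name in list(out):
        if name in _CLAMP_UNIT:
            v = min(1.0, max(0.0, out[name]))
            clamped |= v != out[name]
            out[name] = v
    if "clinical.rr_gcsf" in out and out["clinical.rr_gcsf"] >= 1.0:
        out["clinical.rr_gcsf"] = 1.0 - 1e-12
        clamped = True
    if "costs.los_days" in out and out["costs.los_days"] > cfg.cohort.cycle_length_days:
        out["costs.los_days"] = cfg.cohort.cycle_length_days
        clamped = True
    # RDI probabilities: restore the with-history >= without-history ordering
    a, b = "clinical.p_low_rdi_no_fn", "clinical.p_low_rdi_fn"
    if a in out and b in out and out[a] > out[b]:
        out[a], out[b] = out[b], out[a]
    # FN hospitalisation utility cannot exceed the on-chemotherapy utility
    a, b = "utilities.u_fn_hosp", "utilities.u_chemo"
    if a in out and b in out and out[a] > out[b]:
        out[a] = out[b]
        clamped = True
    return out, clamped


def psa(
    cfg: ScenarioConfig,
    n: Optional[int] = None,
    seed: Optional[int] = None,
    keep_draws: bool = False,
) -> PsaResult:
    """Probabilistic sensitivity analysis with joint independent sampling.

    Every uncertain parameter is drawn once per iteration from its fitted
    distribution; the same draw feeds both strategy arms.  Draws that
    would breach a structural bound are clamped (and counted); more than
    1% clamped iterations logs a warning.
    """
    if n is None:
        n = cfg.psa_iterations
    if seed is None:
        seed = cfg.seed
    if n < 1:
        raise ValidationError(f"n: must be >= 1, got {n}")
    fitted = [fit_distribution(p) for p in cfg.uncertainty]
    fitted.sort(key=lambda p: p.name)
    life_table = resolve_life_table(cfg.life_table)

    arrays = {key: np.empty(n) for key in (
        "pp_cost", "pp_ly", "pp_qaly", "pp_fn_events",
        "sp_cost", "sp_ly", "sp_qaly", "sp_fn_events")}
    drawn = {p.name: np.empty(n) for p in fitted} if keep_draws else {}
    n_clamped = 0

    for i in range(n):
        draws = {}
        for j, p in enumerate(fitted):
            rng = np.random.default_rng([seed, i, j])
            draws[p.name] = float(sample_parameter(p, rng))
        draws, was_clamped = _clamp_draws(draws, cfg)
        cfg_i = cfg
        for name, value in draws.items():
            cfg_i = apply_parameter(cfg_i, name, value)
        risks = build_risk_table(cfg_i.clinical, cfg_i.cohort.n_cycles)
        n_clamped += was_clamped or risks.clamped
        for strategy, prefix in (("PP", "pp"), ("SP", "sp")):
            res = run_strategy(cfg_i, strategy, risks, life_table, with_avoided=False)
            arrays[f"{prefix}_cost"][i] = res.cost
            arrays[f"{prefix}_ly"][i] = res.ly
            arrays[f"{prefix}_qaly"][i] = res.qaly
            arrays[f"{prefix}_fn_events"][i] = res.fn_events
        if keep_draws:
            for name, value in draws.items():
                drawn[name][i] = value

    if n_clamped > 0.01 * n:
        log.warning("PSA: %d of %d iterations required clamping", n_clamped, n)
    curve = ceac(arrays["pp_cost"], arrays["pp_qaly"],
                 arrays["sp_cost"], arrays["sp_qaly"], cfg.wtp_grid)
    return PsaResult(
        seed=seed, n=n, wtp_grid=tuple(cfg.wtp_grid),
        ceac=curve, n_clamped=n_clamped, drawn=drawn, **arrays,
    )
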