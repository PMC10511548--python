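"""Per-cycle febrile-neutropenia risk: calibration and strategy effects.

The published risk input is the probability of at least one FN event over
the whole chemotherapy course for an unprophylaxed patient.  The model
needs per-cycle probabilities, with cycle 1 riskier than later cycles and
a history of FN raising subsequent risk.  ``calibrate_cycle1_risk`` solves
for the cycle-1 probability ``p1`` such that the no-history, no-prophylaxis
path reproduces the course-level risk:

    1 - (1 - p1) * (1 - rr_later * p1)^(n_cycles - 1) = p_total

Prophylaxis multiplies the per-cycle probability by the agent's relative
risk in every cycle where it is active: all cycles under primary
prophylaxis (PP); only cycles after a first FN event under secondary
prophylaxis (SP).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.optimize import brentq

from .errors import CalibrationError
from .params import ClinicalParams

__all__ = [
    "CycleRiskTable",
    "calibrate_cycle1_risk",
    "build_risk_table",
    "per_cycle_fn_prob",
    "rdi_distribution",
]

_RESIDUAL_TOL = 1e-10


@dataclass(frozen=True)
class CycleRiskTable:
    """Baseline (no prophylaxis) per-cycle FN probabilities.

    ``clamped`` flags whether any composed probability had to be capped
    at 1 (can happen under extreme PSA draws of the relative risks).
    """

    p_cycle1: float
    p_later_no_hist: float
    p_later_hist: float
    clamped: bool = False

    def baseline(self, cycle: int, history: bool) -> float:
        if history:
            return self.p_later_hist
        return self.p_cycle1 if cycle == 1 else self.p_later_no_hist


def _course_risk(p1: float, rr_later: float, n_cycles: int) -> float:
    return 1.0 - (1.0 - p1) * (1.0 - rr_later * p1) ** (n_cycles - 1)


def calibrate_cycle1_risk(p_total: float, rr_later: float, n_cycles: int) -> float:
    """Solve for the cycle-1 FN probability reproducing the course risk.

    Conditions on the no-history, no-prophylaxis path.  Uses a bracketed
    root search on [0, min(1, 1/rr_later)]; the residual of the returned
    root is below 1e-10.
    """
    if not (0.0 < p_total < 1.0):
        raise CalibrationError(f"p_total must lie in (0, 1), got {p_total}")
    if rr_later <= 0:
        raise CalibrationError(f"rr_later must be > 0, got {rr_later}")
    if n_cycles < 1:
        raise CalibrationError(f"n_cycles must be >= 1, got {n_cycles}")
    if n_cycles == 1:
        return p_total
    hi = min(1.0, 1.0 / rr_later)

    def f(p1: float) -> float:
        return _course_risk(p1, rr_later, n_cycles) - p_total

    if f(0.0) > 0 or f(hi) < 0:
        raise CalibrationError(
            f"no root in [0, {hi}] for p_total={p_total}, rr_later={rr_later}"
        )
    p1 = brentq(f, 0.0, hi, xtol=1e-15, rtol=8.9e-16)
    if abs(f(p1)) >= _RESIDUAL_TOL:
        raise CalibrationError(f"calibration residual {f(p1):.3e} exceeds {_RESIDUAL_TOL}")
    return p1


def build_risk_table(clinical: ClinicalParams, n_cycles: int) -> CycleRiskTable:
    """Calibrate cycle-1 risk and compose the later-cycle probabilities."""
    p1 = calibrate_cycle1_risk(clinical.baseline_fn_risk, clinical.rr_later_cycles,
                               n_cycles)
    later = clinical.rr_later_cycles * p1
    hist = clinical.rr_history * min(1.0, later)
    clamped = later > 1.0 or hist > 1.0
    return CycleRiskTable(
        p_cycle1=p1,
        p_later_no_hist=min(1.0, later),
        p_later_hist=min(1.0, hist),
        clamped=clamped,
    )


def per_cycle_fn_prob(
    cycle: int,
    history: bool,
    strategy: str,
    agent_rr: float,
    table: CycleRiskTable,
    rr_scale: str = "probability",
) -> float:
    """FN probability for one cycle, history state, and prophylaxis strategy.

    ``strategy`` is PP (G-CSF every cycle), SP (G-CSF only once an FN event
    has occurred) or NONE (never).  ``rr_scale`` selects whether the agent's
    relative risk multiplies the probability directly (default) or acts on
    the instantaneous rate, p -> 1 - (1-p)^rr.
    """
    if cycle < 1:
        raise ValueError(f"cycle index must be >= 1, got {cycle}")
    if strategy not in ("PP", "SP", "NONE"):
        raise ValueError(f"strategy must be PP, SP or NONE, got {strategy!r}")
    if not (0.0 < agent_rr <= 1.0):
        raise ValueError(f"agent_rr must lie in (0, 1], got {agent_rr}")
    p = table.baseline(cycle, history)
    active = strategy == "PP" or (strategy == "SP" and history)
    if active:
        if rr_scale == "probability":
            p = agent_rr * p
        else:
            p = 1.0 - (1.0 - p) ** agent_rr
    return min(1.0, max(0.0, p))


def rdi_distribution(ever_fn: bool, clinical: ClinicalParams) -> float:
    """Probability of a below-threshold relative dose intensity given
    whether the patient ever experienced FN during chemotherapy."""
    return clinical.p_low_rdi_fn if ever_fn else clinical.p_low_rdi_no_fn
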