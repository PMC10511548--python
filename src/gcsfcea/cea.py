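"""Incremental cost-effectiveness statistics.

Incremental comparisons use secondary prophylaxis (SP) as the reference:
deltas are PP minus SP.  Three ICERs are reported — cost per FN event
avoided, per life year (LY) gained, and per QALY gained.  When PP is both
cheaper and more effective it dominates and no ICER is defined; the
reverse classifies as dominated.  Net monetary benefit (NMB) at a
willingness-to-pay (WTP) threshold underlies the cost-effectiveness
acceptability curve (CEAC).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cohort import StrategyOutcome
from .errors import ValidationError

__all__ = [
    "CEResult",
    "DOMINANT",
    "DOMINATED",
    "EQUIVALENT",
    "NOT_EFFECTIVE",
    "incremental",
    "nmb",
    "ceac",
    "base_case_table",
]

DOMINANT = "dominant"
DOMINATED = "dominated"
EQUIVALENT = "equivalent"
NOT_EFFECTIVE = "not effective"

Icer = Union[float, str, None]


@dataclass(frozen=True)
class CEResult:
    """Incremental comparison of PP vs SP for one scenario."""

    delta_cost: float
    delta_fn_avoided: float
    delta_ly: float
    delta_qaly: float
    status: str  # icer | dominant | dominated | equivalent
    icer_fn: Icer = None
    icer_ly: Icer = None
    icer_qaly: Icer = None


def _ratio(delta_cost: float, delta_effect: float) -> Icer:
    if delta_effect == 0.0:
        if delta_cost == 0.0:
            return EQUIVALENT
        return NOT_EFFECTIVE if delta_cost > 0 else None
    return delta_cost / delta_effect


def incremental(pp: StrategyOutcome, sp: StrategyOutcome) -> CEResult:
    """Deltas (PP - SP), dominance classification, and ICERs.

    FN effect delta uses the events-avoided convention where both outcomes
    carry it; otherwise it falls back to SP events minus PP events (the two
    are identical because the no-prophylaxis reference cancels).
    """
    d_cost = pp.cost - sp.cost
    if pp.fn_events_avoided is not None and sp.fn_events_avoided is not None:
        d_fn = pp.fn_events_avoided - sp.fn_events_avoided
    else:
        d_fn = sp.fn_events - pp.fn_events
    d_ly = pp.ly - sp.ly
    d_qaly = pp.qaly - sp.qaly
    effects = (d_fn, d_ly, d_qaly)

    if d_cost == 0.0 and all(e == 0.0 for e in effects):
        return CEResult(d_cost, d_fn, d_ly, d_qaly, EQUIVALENT)
    if d_cost < 0.0 and all(e > 0.0 for e in effects):
        return CEResult(d_cost, d_fn, d_ly, d_qaly, DOMINANT)
    if d_cost > 0.0 and all(e < 0.0 for e in effects):
        return CEResult(d_cost, d_fn, d_ly, d_qaly, DOMINATED)
    return CEResult(
        d_cost, d_fn, d_ly, d_qaly, "icer",
        icer_fn=_ratio(d_cost, d_fn),
        icer_ly=_ratio(d_cost, d_ly),
        icer_qaly=_ratio(d_cost, d_qaly),
    )


def nmb(outcome: StrategyOutcome, wtp: float) -> float:
    """Net monetary benefit: wtp x QALY - cost."""
    if wtp < 0:
        raise ValidationError(f"wtp: must be >= 0, got {wtp}")
    return wtp * outcome.qaly - outcome.cost


def ceac(
    pp_cost: np.ndarray,
    pp_qaly: np.ndarray,
    sp_cost: np.ndarray,
    sp_qaly: np.ndarray,
    wtp_grid: Sequence[float],
) -> np.ndarray:
    """Cost-effectiveness acceptability curve for PP over a WTP grid.

    For each threshold, the fraction of paired PSA draws in which PP has a
    strictly higher net monetary benefit than SP (ties count against PP).
    """
    pp_cost = np.asarray(pp_cost, dtype=float)
    pp_qaly = np.asarray(pp_qaly, dtype=float)
    sp_cost = np.asarray(sp_cost, dtype=float)
    sp_qaly = np.asarray(sp_qaly, dtype=float)
    if pp_cost.size == 0:
        raise ValidationError("ceac: empty draw set")
    if not (pp_cost.shape == pp_qaly.shape == sp_cost.shape == sp_qaly.shape):
        raise ValidationError("ceac: draw arrays must share one shape")
    wtp = np.asarray(list(wtp_grid), dtype=float)
    d_nmb = wtp[:, None] * (pp_qaly - sp_qaly)[None, :] - (pp_cost - sp_cost)[None, :]
    return (d_nmb > 0.0).mean(axis=1)


def base_case_table(
    pp: StrategyOutcome,
    sp: StrategyOutcome,
    result: Optional[CEResult] = None,
) -> pd.DataFrame:
    """Two-row table mirroring the published base-case layout: costs, FN
    events avoided, LYs, QALYs and the three ICERs (SP as reference)."""
    if result is None:
        result = incremental(pp, sp)

    def icer_cell(value: Icer) -> object:
        if result.status == DOMINANT:
            return "Dominates"
        if result.status == DOMINATED:
            return "Dominated"
        if result.status == EQUIVALENT:
            return "Equivalent"
        return value

    rows = [
        {
            "strategy": "Primary prophylaxis",
            "cost": pp.cost,
            "fn_events_avoided": pp.fn_events_avoided,
            "ly": pp.ly,
            "qaly": pp.qaly,
            "icer_fn_avoided": icer_cell(result.icer_fn),
            "icer_ly": icer_cell(result.icer_ly),
            "icer_qaly": icer_cell(result.icer_qaly),
        },
        {
            "strategy": "Secondary prophylaxis",
            "cost": sp.cost,
            "fn_events_avoided": sp.fn_events_avoided,
            "ly": sp.ly,
            "qaly": sp.qaly,
            "icer_fn_avoided": "Reference",
            "icer_ly": "Reference",
            "icer_qaly": "Reference",
        },
    ]
    return pd.DataFrame(rows)
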