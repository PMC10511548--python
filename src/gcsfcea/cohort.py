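"""Deterministic cohort engine and patient-level microsimulation oracle.

The model runs in two phases over a lifetime horizon:

* Chemotherapy (cycle 1 decision tree, later cycles a Markov cycle tree of
  3-week cycles): each cycle a patient may have a febrile-neutropenia (FN)
  event, treated inpatient; FN carries a case fatality applied at the end
  of the cycle, and survivors carry an FN history that raises later risk.
  Costs (prophylaxis drug + FN admission) accrue only here.
* Post-chemotherapy (annual Markov cycles): survivors split once into
  low/high relative-dose-intensity (RDI) strata from their FN history; for
  the first 20 years the cancer-related annual death probability (times
  the low-RDI hazard ratio where applicable) adds to the age- and
  sex-specific background probability, after which patients are considered
  cured and only background mortality applies.

Discounting is applied at mid-cycle / mid-year by default.  During
chemotherapy, deaths occur at the end of the cycle, so decedents accrue
that cycle's life-time and utility; in the annual phase accrual goes to
the survivors of each year (an end-of-year death convention), which makes
discounted life years equal the classic annuity sum over the survival
curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ValidationError
from .lifetables import LifeTable, resolve_life_table
from .params import ScenarioConfig
from .risk import CycleRiskTable, build_risk_table, per_cycle_fn_prob, rdi_distribution

__all__ = [
    "ChemoState",
    "StrategyOutcome",
    "MicrosimResult",
    "annual_prob_from_5yr_death",
    "run_chemo_phase",
    "run_post_chemo_phase",
    "run_strategy",
    "run_base_case",
    "simulate_individuals",
]

DAYS_PER_YEAR = 365.25
_OCCUPANCY_TOL = 1e-9


def annual_prob_from_5yr_death(p5: float, t: float = 5.0) -> float:
    """Convert a t-year death probability to an annual probability via the
    constant-rate identity r = -ln(1-P)/t, returning 1 - exp(-r)."""
    if not (0.0 <= p5 < 1.0):
        raise ValidationError(f"p5: must lie in [0, 1), got {p5}")
    if t <= 0:
        raise ValidationError(f"t: must be > 0, got {t}")
    rate = -np.log1p(-p5) / t
    return float(-np.expm1(-rate))


@dataclass
class ChemoState:
    """Cohort occupancy and accruals at the end of the chemotherapy phase."""

    alive_no_hist: float
    alive_hist: float
    dead: float
    cycle: int
    cost: float = 0.0
    ly: float = 0.0
    qaly: float = 0.0
    fn_events: float = 0.0
    fn_deaths: float = 0.0

    def check(self) -> None:
        total = self.alive_no_hist + self.alive_hist + self.dead
        if abs(total - 1.0) > _OCCUPANCY_TOL or min(
            self.alive_no_hist, self.alive_hist, self.dead
        ) < -_OCCUPANCY_TOL:
            raise ValidationError(
                f"occupancy drift: states sum to {total!r} "
                f"({self.alive_no_hist}, {self.alive_hist}, {self.dead})"
            )


@dataclass(frozen=True)
class StrategyOutcome:
    """Expected per-patient results for one prophylaxis strategy."""

    cost: float
    ly: float
    qaly: float
    fn_events: float
    fn_deaths: float
    fn_events_avoided: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("cost", "ly", "qaly", "fn_events", "fn_deaths"):
            v = getattr(self, name)
            if v < -1e-12:
                raise ValidationError(f"{name}: must be >= 0, got {v}")
        if self.qaly > self.ly + 1e-9:
            raise ValidationError(f"qaly ({self.qaly}) exceeds ly ({self.ly})")


def _discount_factor(rate: float, t: float) -> float:
    return (1.0 + rate) ** -t


def _cycle_times(cfg: ScenarioConfig, cycle: int) -> float:
    """Discounting time (years) for accruals of a chemotherapy cycle."""
    dt = cfg.cohort.cycle_length_days / DAYS_PER_YEAR
    offset = 0.5 if cfg.half_cycle == "mid" else 0.0
    return (cycle - offset) * dt


def run_chemo_phase(
    cfg: ScenarioConfig,
    strategy: str,
    risks: Optional[CycleRiskTable] = None,
) -> ChemoState:
    """Run the chemotherapy phase (decision tree + Markov cycle tree).

    Per cycle: FN events occur with the strategy-adjusted probability; FN
    cases incur the admission cost, spend the length of stay at the FN
    utility, and face the case fatality at the end of the cycle; survivors
    of an FN event carry a history thereafter.  Prophylaxis drug cost
    accrues to everyone under PP and to patients with a history under SP.
    """
    if risks is None:
        risks = build_risk_table(cfg.clinical, cfg.cohort.n_cycles)
    dt = cfg.cohort.cycle_length_days / DAYS_PER_YEAR
    gcsf_cost = cfg.costs.cycle_drug_cost()
    hosp_cost = cfg.costs.fn_hospitalisation_cost
    fatality = cfg.mortality.fn_case_fatality
    u_full = cfg.utilities.u_chemo * dt
    u_fn = (
        cfg.costs.los_days * cfg.utilities.u_fn_hosp
        + (cfg.cohort.cycle_length_days - cfg.costs.los_days) * cfg.utilities.u_chemo
    ) / DAYS_PER_YEAR

    st = ChemoState(alive_no_hist=1.0, alive_hist=0.0, dead=0.0, cycle=0)
    for k in range(1, cfg.cohort.n_cycles + 1):
        t = _cycle_times(cfg, k)
        fc = _discount_factor(cfg.discount_rate_costs, t)
        fe = _discount_factor(cfg.discount_rate_effects, t)
        p_nh = per_cycle_fn_prob(k, False, strategy, cfg.clinical.rr_gcsf, risks,
                                 cfg.rr_scale)
        p_h = per_cycle_fn_prob(k, True, strategy, cfg.clinical.rr_gcsf, risks,
                                cfg.rr_scale)
        fn_nh = st.alive_no_hist * p_nh
        fn_h = st.alive_hist * p_h
        fn = fn_nh + fn_h
        alive = st.alive_no_hist + st.alive_hist

        if strategy == "PP":
            on_drug = alive
        elif strategy == "SP":
            on_drug = st.alive_hist
        else:
            on_drug = 0.0
        st.cost += fc * (on_drug * gcsf_cost + fn * hosp_cost)

        # deaths occur at end of cycle: everyone alive at cycle start
        # accrues the full cycle's life-time and utility
        st.ly += fe * alive * dt
        st.qaly += fe * ((alive - fn) * u_full + fn * u_fn)

        deaths = fn * fatality
        st.fn_events += fn
        st.fn_deaths += deaths
        st.alive_no_hist -= fn_nh
        st.alive_hist = st.alive_hist - fn_h + fn * (1.0 - fatality)
        st.dead += deaths
        st.cycle = k
        st.check()
    return st


def _post_chemo_survival(
    qx: np.ndarray,
    entry_age: int,
    excess_mortality: float,
    cure_horizon: int,
) -> np.ndarray:
    """Survival curve S(k) = P(alive after k years), k = 1..K, where the
    annual death probability is the background qx plus the cancer-related
    excess (clamped at 1) during the cure horizon."""
    terminal = qx.size - 1
    n_years = max(terminal - entry_age, 1)
    ages = np.minimum(entry_age + np.arange(n_years), terminal)
    q = qx[ages].astype(float).copy()
    horizon = min(cure_horizon, n_years)
    q[:horizon] = np.minimum(1.0, q[:horizon] + excess_mortality)
    q[-1] = max(q[-1], qx[terminal])
    return np.cumprod(1.0 - q)


def _post_chemo_accrual(
    cfg: ScenarioConfig,
    survival: np.ndarray,
    t0: float,
) -> tuple[float, float]:
    """Discounted (LY, QALY) per member of one post-chemo stratum."""
    k = np.arange(1, survival.size + 1)
    offset = 0.5 if cfg.half_cycle == "mid" else 0.0
    disc = (1.0 + cfg.discount_rate_effects) ** -(t0 + k - offset)
    u = np.full(survival.size, cfg.utilities.u_post_later)
    u[0] = cfg.utilities.u_post_year1
    ly = float(np.sum(survival * disc))
    qaly = float(np.sum(survival * u * disc))
    return ly, qaly


def run_post_chemo_phase(
    cfg: ScenarioConfig,
    entry: ChemoState,
    life_table: Optional[LifeTable] = None,
) -> tuple[float, float]:
    """Discounted (LY, QALY) contribution of the annual post-chemo phase.

    Survivors are split once into low/high RDI strata from their FN-history
    mix; the low stratum's cancer mortality is scaled by the hazard ratio.
    No costs accrue after chemotherapy.
    """
    if life_table is None:
        life_table = resolve_life_table(cfg.life_table)
    entry.check()
    p_low_h = rdi_distribution(True, cfg.clinical)
    p_low_nh = rdi_distribution(False, cfg.clinical)
    low = entry.alive_hist * p_low_h + entry.alive_no_hist * p_low_nh
    high = (entry.alive_hist + entry.alive_no_hist) - low

    t0 = cfg.cohort.n_cycles * cfg.cohort.cycle_length_days / DAYS_PER_YEAR
    age0 = int(round(cfg.cohort.entry_age))
    ly = qaly = 0.0
    for sex, w_sex in (("f", cfg.cohort.sex_mix), ("m", 1.0 - cfg.cohort.sex_mix)):
        if w_sex == 0.0:
            continue
        qx = life_table.qx(sex)
        for occ, hr in ((low, cfg.mortality.hr_low_rdi), (high, 1.0)):
            if occ == 0.0:
                continue
            surv = _post_chemo_survival(
                qx, age0, cfg.mortality.cancer_annual_mortality * hr,
                cfg.cohort.cure_horizon_years,
            )
            s_ly, s_qaly = _post_chemo_accrual(cfg, surv, t0)
            ly += w_sex * occ * s_ly
            qaly += w_sex * occ * s_qaly
    return ly, qaly


def run_strategy(
    cfg: ScenarioConfig,
    strategy: str,
    risks: Optional[CycleRiskTable] = None,
    life_table: Optional[LifeTable] = None,
    with_avoided: bool = True,
) -> StrategyOutcome:
    """Full deterministic cohort run for one prophylaxis strategy.

    ``fn_events_avoided`` is measured against a no-prophylaxis run of the
    same scenario (the convention of the published result tables); pass
    ``with_avoided=False`` to skip that extra run.
    """
    if risks is None:
        risks = build_risk_table(cfg.clinical, cfg.cohort.n_cycles)
    if life_table is None:
        life_table = resolve_life_table(cfg.life_table)
    chemo = run_chemo_phase(cfg, strategy, risks)
    ly_post, qaly_post = run_post_chemo_phase(cfg, chemo, life_table)
    avoided = None
    if with_avoided:
        if strategy == "NONE":
            avoided = 0.0
        else:
            none = run_chemo_phase(cfg, "NONE", risks)
            avoided = none.fn_events - chemo.fn_events
    return StrategyOutcome(
        cost=chemo.cost,
        ly=chemo.ly + ly_post,
        qaly=chemo.qaly + qaly_post,
        fn_events=chemo.fn_events,
        fn_deaths=chemo.fn_deaths,
        fn_events_avoided=avoided,
    )


def run_base_case(cfg: ScenarioConfig) -> dict[str, StrategyOutcome]:
    """Run PP, SP and the no-prophylaxis reference on one scenario."""
    risks = build_risk_table(cfg.clinical, cfg.cohort.n_cycles)
    lt = resolve_life_table(cfg.life_table)
    none = run_strategy(cfg, "NONE", risks, lt, with_avoided=False)
    out = {"NONE": none}
    for strategy in ("PP", "SP"):
        res = run_strategy(cfg, strategy, risks, lt, with_avoided=False)
        out[strategy] = StrategyOutcome(
            cost=res.cost, ly=res.ly, qaly=res.qaly, fn_events=res.fn_events,
            fn_deaths=res.fn_deaths,
            fn_events_avoided=none.fn_events - res.fn_events,
        )
    return out


# ---------------------------------------------------------------------------
# patient-level microsimulation (testing oracle)


@dataclass(frozen=True)
class MicrosimResult:
    """Monte-Carlo estimate of a StrategyOutcome with standard errors."""

    outcome: StrategyOutcome
    se: dict = field(default_factory=dict)
    n: int = 0


def simulate_individuals(
    cfg: ScenarioConfig,
    strategy: str,
    n: int,
    seed: int,
) -> MicrosimResult:
    """Bernoulli patient-level simulation of the identical event logic.

    Serves as an independent oracle for the cohort engine: means converge
    to the cohort expectations, and the returned standard errors quantify
    the Monte-Carlo noise.  Post-chemotherapy death years are drawn by
    inverting each stratum's survival curve, which is distributionally
    identical to year-by-year Bernoulli draws.
    """
    if n < 1:
        raise ValidationError(f"n: must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    risks = build_risk_table(cfg.clinical, cfg.cohort.n_cycles)
    lt = resolve_life_table(cfg.life_table)
    dt = cfg.cohort.cycle_length_days / DAYS_PER_YEAR
    gcsf_cost = cfg.costs.cycle_drug_cost()
    hosp_cost = cfg.costs.fn_hospitalisation_cost
    fatality = cfg.mortality.fn_case_fatality
    u_full = cfg.utilities.u_chemo * dt
    u_fn = (
        cfg.costs.los_days * cfg.utilities.u_fn_hosp
        + (cfg.cohort.cycle_length_days - cfg.costs.los_days) * cfg.utilities.u_chemo
    ) / DAYS_PER_YEAR

    alive = np.ones(n, dtype=bool)
    hist = np.zeros(n, dtype=bool)
    cost = np.zeros(n)
    ly = np.zeros(n)
    qaly = np.zeros(n)
    events = np.zeros(n)
    deaths = np.zeros(n)

    for k in range(1, cfg.cohort.n_cycles + 1):
        t = _cycle_times(cfg, k)
        fc = _discount_factor(cfg.discount_rate_costs, t)
        fe = _discount_factor(cfg.discount_rate_effects, t)
        p_nh = per_cycle_fn_prob(k, False, strategy, cfg.clinical.rr_gcsf, risks,
                                 cfg.rr_scale)
        p_h = per_cycle_fn_prob(k, True, strategy, cfg.clinical.rr_gcsf, risks,
                                cfg.rr_scale)
        p = np.where(hist, p_h, p_nh)
        fn = alive & (rng.random(n) < p)
        if strategy == "PP":
            on_drug = alive
        elif strategy == "SP":
            on_drug = alive & hist
        else:
            on_drug = np.zeros(n, dtype=bool)
        cost += fc * (on_drug * gcsf_cost + fn * hosp_cost)
        ly += fe * alive * dt
        qaly += fe * alive * np.where(fn, u_fn, u_full)
        die = fn & (rng.random(n) < fatality)
        events += fn
        deaths += die
        hist |= fn
        alive &= ~die

    # post-chemo: stratify and draw death years from the survival curve
    p_low = np.where(hist, rdi_distribution(True, cfg.clinical),
                     rdi_distribution(False, cfg.clinical))
    low = rng.random(n) < p_low
    sex_f = rng.random(n) < cfg.cohort.sex_mix
    t0 = cfg.cohort.n_cycles * cfg.cohort.cycle_length_days / DAYS_PER_YEAR
    age0 = int(round(cfg.cohort.entry_age))
    u_draw = rng.random(n)
    offset = 0.5 if cfg.half_cycle == "mid" else 0.0

    for sex, sex_mask in (("f", sex_f), ("m", ~sex_f)):
        qx = lt.qx(sex)
        for is_low, hr in ((True, cfg.mortality.hr_low_rdi), (False, 1.0)):
            mask = alive & sex_mask & (low == is_low)
            if not mask.any():
                continue
            surv = _post_chemo_survival(
                qx, age0, cfg.mortality.cancer_annual_mortality * hr,
                cfg.cohort.cure_horizon_years,
            )
            kk = np.arange(1, surv.size + 1)
            disc = (1.0 + cfg.discount_rate_effects) ** -(t0 + kk - offset)
            u_year = np.full(surv.size, cfg.utilities.u_post_later)
            u_year[0] = cfg.utilities.u_post_year1
            cum_ly = np.concatenate(([0.0], np.cumsum(disc)))
            cum_qaly = np.concatenate(([0.0], np.cumsum(u_year * disc)))
            # years survived = #{k : S(k) > u}; ascending view for searchsorted
            asc = surv[::-1]
            years = surv.size - np.searchsorted(asc, u_draw[mask], side="right")
            ly[mask] += cum_ly[years]
            qaly[mask] += cum_qaly[years]

    means = {}
    ses = {}
    for name, arr in (("cost", cost), ("ly", ly), ("qaly", qaly),
                      ("fn_events", events), ("fn_deaths", deaths)):
        means[name] = float(np.mean(arr))
        ses[name] = float(np.std(arr, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    outcome = StrategyOutcome(
        cost=means["cost"], ly=means["ly"], qaly=means["qaly"],
        fn_events=means["fn_events"], fn_deaths=means["fn_deaths"],
    )
    return MicrosimResult(outcome=outcome, se=ses, n=n)
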