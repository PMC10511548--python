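# Methods

This note records how the model is specified, which choices were open and
how they were made, and what the validation does and does not establish.

## Model structure and assumptions

The model is a hybrid decision-tree/Markov cohort model run as
expectations over a closed cohort (no interaction between patients).

**Chemotherapy phase.** Six cycles of 21 days for all three cancers (the
R-CHOP course for NHL is 6 × 21 days; cycle counts for the BC and NSCLC
regimens are configurable via `CohortProfile.n_cycles`). States are
{alive, no FN history}, {alive, FN history}, {dead}. Per cycle, in order:

1. FN occurs with the per-cycle probability (below); at most one event
   per cycle.
2. FN cases incur the lump admission cost; prophylaxis drug cost accrues
   to everyone under PP and to patients with an FN history under SP (the
   SP trigger: no G-CSF until the first FN event, G-CSF every cycle
   thereafter).
3. FN cases die with the case-fatality probability at the end of the
   cycle; all deaths during chemotherapy are FN-related.
4. Everyone alive at the cycle start accrues the full cycle of life-time
   and utility (deaths happen at cycle end): `u_chemo` for the cycle,
   except FN cases who spend the admission length of stay at `u_fn_hosp`.
5. Survivors of an FN event carry the history state onward.

**Per-cycle risk.** The published input is the course-level FN risk `P`
for an unprophylaxed patient. The cycle-1 probability solves
`1 − (1−p1)·(1−RR_later·p1)^(n−1) = P` on the no-history path (patients
with a history follow the `RR_hist`-multiplied risk instead; the
calibration deliberately conditions on the no-history path, so the
course-level risk is reproduced exactly for a patient who never
accumulates history). The root is found by bracketed root search on
`[0, min(1, 1/RR_later)]` with residual < 1e-10. Relative risks multiply
probabilities directly and are clamped at 1; a `rr_scale="rate"` dial
applies them on the log-survival scale instead (`p → 1−(1−p)^RR`).

**Post-chemotherapy phase.** Annual cycles to a terminal age of 110.
Survivors are assigned once, at chemotherapy completion, to low/high RDI
strata with probabilities conditional on ever-FN status (the history mix
is carried exactly). For 20 years the cancer-related annual death
probability — multiplied by the low-RDI hazard ratio in the low stratum —
adds to the age- and sex-specific background probability, clamped at 1;
from year 21 patients are cured and only background mortality applies.
Utilities are `u_post_year1` in the first year and `u_post_later`
thereafter. No costs accrue after chemotherapy (prophylaxis-independent
costs cancel in the incremental comparison). Female and male sub-cohorts
are run separately and weighted by the cohort sex mix.

**Accrual conventions.** Discounting is at mid-cycle/mid-year
(`half_cycle="mid"`; `"none"` discounts at cycle end). During
chemotherapy decedents accrue their final cycle (end-of-cycle deaths); in
the annual phase accrual goes to the survivors of each year, so
discounted life years equal the annuity sum Σ S(k)/(1+d)^(t₀+k−½) over
the survival curve — the identity the test suite checks against a closed
form. The phase conventions differ deliberately: the chemotherapy phase
states when deaths happen (cycle end), while the annual phase uses the
standard survivor-annuity form.

**Mortality conversion.** Published cancer mortality derived from 5-year
survival is converted through the constant-rate identity
`r = −ln(1−P)/t`, `p1 = 1−exp(−r)`; the package exposes this as
`annual_prob_from_5yr_death`.

## Parameters

All published clinical inputs (course-level FN risk per cancer, cycle and
history relative risks, agent relative risks, RDI probabilities,
utilities, cancer mortality, FN case fatality, low-RDI hazard ratio) are
carried with their base values, ranges and distribution families in
`gcsfcea.datasets` and flow into every fixture with provenance `paper`.

Ranges are interpreted as 95% intervals. Betas are fitted by moment
matching (mean = base, sd = range/3.92) — including the one range with a
zero lower bound — and lognormals by log-mean = ln(base),
log-sd = (ln high − ln low)/3.92. Moment matching was preferred over
exact interval inversion because it is closed-form and reproducible; for
the published lognormal inputs the fitted 95% interval recovers the
printed bounds within 3% (tested). The pegfilgrastim relative risk was
published without a range; its fixture range carries over the filgrastim
log-scale uncertainty (0.179–0.339 around 0.25).

Choices the original analysis did not publish are fixture-level settings
with provenance `fixture`, chosen once:

* **Entry age / sex mix** (per the predecessor US model's cohorts):
  BC 50 y, 100% female; NSCLC 65 y, 35% female; NHL 62 y, 45% female.
* **Discount rates** per national HTA convention: Austria 5%/yr, France
  2.5%/yr, Germany 3%/yr, same rate for costs and effects, configurable.
* **Life tables**: synthetic Gompertz stand-ins for national period life
  tables, `qx = 1 − exp(−a·e^{b·age})` with a male hazard factor,
  parameters set per country for realistic European life expectancies
  (e.g. ~34 remaining years for a 50-year-old woman). A real national
  table can be supplied as an `age,sex,qx` CSV.
* **Dosing/LOS scaffold**: filgrastim 5 µg/kg/day rounded up to whole
  300 µg vials, 5 doses per cycle (configurable 1–14), 70 kg reference
  weight; pegfilgrastim one dose per cycle; 8-day FN admission. The
  admission cost is a lump sum, so the length of stay enters through the
  utility weighting only; the patient's weight enters through vial
  rounding, which keeps both live in the sensitivity analyses.
* **OWSA ranges without published values**: ±20% on the calibrated costs,
  LOS 5–11 days, weight 60–90 kg, discount rate 0–5%. The discount rate
  is varied in the OWSA but held at base in the PSA (family `fixed`).

## Cost calibration

The unpublished cost inputs are identified, not assumed. For a fixed
scenario the total discounted cost under strategy *s* is exactly

    total(s) = A(s) · gcsf_cost_per_cycle + B(s) · fn_admission_cost

with `A` the expected discounted number of prophylaxis cycles delivered
and `B` the expected discounted number of FN admissions; both are read
off the engine by running the chemotherapy phase with unit costs. The
2×2 system against the published PP and SP totals is solved per
country × cancer × agent block (condition numbers ~10–40; the solve
aborts above 10⁶ or on a negative solution). All 18 blocks solve
positive, and rerunning each base case reproduces all 36 published cost
cells to machine precision (tested at €0.5). Solved filgrastim per-cycle
costs fall between ~€190 and ~€580 — within the 1×–20× sanity band around
the €55.54 per-vial list price the original discussion quotes. Because
each block is calibrated independently, the solved admission cost differs
between the two agent blocks of one country; the calibration report lists
all solved values rather than reconciling them.

The published LY/QALY columns are *not* calibration targets: they depend
on the unpublished entry ages, sex mixes, national life tables and
discount rates. With the fixture choices above the model's incremental
effects land close to the published ones (e.g. Austria BC filgrastim
ΔQALY 0.058 vs 0.063 published) but absolute LYs differ by O(1) year;
those discrepancies are reported by the examples, not absorbed.

## Sensitivity analyses

**OWSA** reruns the full base case at each parameter's bounds, holding
the rest at base, and ranks by the swing on the cost-per-QALY scale with
dominance mapped to 0 for ordering. Bounds that violate structural
invariants are skipped with a warning.

**PSA** draws all parameters jointly and independently (no correlation
structure was published). Each (iteration, parameter) pair gets its own
counter-derived random substream, so results are bit-reproducible and
independent of evaluation order. Draws are shared between the PP and SP
arms within an iteration. Structural clamps: probabilities to [0,1], the
agent RR below 1, LOS to the cycle length, the FN-hospitalisation utility
to at most the on-chemotherapy utility; the low-RDI probability pair is
order-restored by swapping when a draw inverts the with/without-history
ordering (preserving the structural inequality without inventing a
copula). Clamped iterations are counted and a >1% rate logs a warning; at
the shipped ranges the rate is 0.

## Validation and what it shows

The microsimulation oracle (`simulate_individuals`) implements the same
event logic patient-by-patient — Bernoulli FN events and deaths, RDI and
sex assignment, and post-chemotherapy death years drawn by inverting each
stratum's survival curve (distributionally identical to year-by-year
Bernoulli draws). The suite checks cohort-vs-microsimulation agreement at
n = 10⁶ per fixture and strategy within 3 Monte-Carlo standard errors;
because that is 144 simultaneous 3-SE comparisons, a comparison only
counts as a failure when it exceeds the bound under two independent
seeds (a systematic discrepancy repeats; a chance excursion does not).
Further structural checks: occupancy conservation to 1e-12, QALY ≤ LY
everywhere, monotone effects of discounting, exact annuity and
life-expectancy identities for flat-hazard and zero-risk cases, cure
behaviour beyond year 20, and the risk- and mortality-conversion round
trips.

Passing these establishes internal consistency with the published inputs
and totals — not external validity. The synthetic layer emulates the
published study's conditions (its parameter point estimates and ranges,
its cost totals); it does not capture regimen-specific cycle counts per
cancer, patient-level FN risk factors, outpatient FN management,
G-CSF adverse events, correlated parameter uncertainty, or real national
life tables, and the absolute LY/QALY levels inherit the fixture
demographic choices.

## Problem sizes and numerics

Default problem sizes: 1000 PSA iterations per scenario (the size the
original analysis used), 10⁶ microsimulation patients for oracle checks,
a 110-year terminal age. The acceptance script runs the nine filgrastim
scenarios at those sizes in well under a minute on one CPU. Root solving
uses bracketed Brent iteration (residual < 1e-10); the cost solve guards
on condition number; occupancy drift beyond 1e-9 raises rather than
renormalises. The run manifest written by the CLI contains no timestamp
so that reruns are byte-identical.
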