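# gcsfcea

Cost-effectiveness modelling of granulocyte colony-stimulating factor
(G-CSF) prophylaxis for chemotherapy-induced febrile neutropenia (FN).

FN — fever with a low neutrophil count during myelosuppressive
chemotherapy — typically means an inpatient admission, carries a real case
fatality, and forces dose delays and reductions (a low relative dose
intensity, RDI) that worsen long-term cancer survival. G-CSFs such as
filgrastim and pegfilgrastim cut the per-cycle FN risk sharply, and the
arrival of biosimilars has changed the economics of giving them to every
patient from cycle 1 (*primary prophylaxis*, PP) rather than only after a
first FN event (*secondary prophylaxis*, SP). This package re-implements,
as a tested Python library, a published European decision-tree/Markov
cohort model comparing PP and SP with biosimilar filgrastim or
pegfilgrastim in breast cancer (BC), non-small cell lung cancer (NSCLC)
and non-Hodgkin's lymphoma (NHL) for Austria, France and Germany. It is
aimed at health-economics and HTA analysts who want a transparent,
scriptable version of that model — to reproduce it, vary it, or recalibrate
it to another health system.

## The model

* **Chemotherapy phase** — six 3-week cycles. Cycle 1 is a decision tree
  (PP vs SP); cycles 2–6 are a Markov cycle tree over
  {alive without FN history, alive with FN history, dead}. The cycle-1 FN
  probability `p1` is calibrated from the published course-level risk
  `P` by solving `1 − (1−p1)·(1−RR_later·p1)^(n−1) = P`; a history of FN
  multiplies later-cycle risk by `RR_hist`, and active prophylaxis by the
  agent's relative risk (0.42 filgrastim, 0.25 pegfilgrastim). FN events
  are inpatient admissions with a lump cost and a case fatality applied at
  the end of the cycle.
* **Post-chemotherapy phase** — annual Markov cycles over a lifetime
  horizon. Survivors split once into low/high RDI strata (history of FN
  raises the low-RDI probability); cancer-related annual mortality — times
  a hazard ratio in the low-RDI stratum — adds to age- and sex-specific
  background mortality for 20 years, after which patients are considered
  cured. Utilities weight life years into QALYs; costs and effects are
  discounted at mid-cycle/mid-year.
* **Outputs** — per-strategy discounted cost, LYs, QALYs, FN events (and
  events avoided vs no prophylaxis), FN deaths; incremental
  cost-effectiveness ratios ΔC/ΔE per FN event avoided, per LY and per
  QALY with dominance classification; net monetary benefit
  `NMB = λ·QALY − cost`; tornado-style one-way sensitivity analysis; and a
  probabilistic sensitivity analysis (PSA) with cost-effectiveness
  acceptability curves (CEAC).
* **Calibration** — the original analysis published its clinical inputs
  and base-case totals but not the country cost tables. Both strategies'
  totals are linear in the two unknown costs (G-CSF cost per cycle, FN
  admission cost), so the pair is identified per scenario by a 2×2 linear
  solve against the published totals; clinical inputs are never tuned.
  The 18 calibrated country × cancer × agent scenarios ship as JSON
  fixtures.

A patient-level microsimulation of the identical event logic serves as an
independent oracle: cohort expectations agree with simulated means within
Monte-Carlo error (see `examples/microsim_check.py`).

## Worked example

```sh
python examples/base_case.py
```

```
scenario: austria_bc_filgrastim   status: icer
             strategy   cost  fn_events_avoided        ly     qaly icer_fn_avoided      icer_ly     icer_qaly
  Primary prophylaxis 1567.0           0.156381 11.354444 9.473879     5376.238181  8520.351504  10071.515884
Secondary prophylaxis  980.0           0.047197 11.285550 9.415595       Reference    Reference     Reference

PP costs +587 EUR and gains 0.058 QALYs per patient vs SP -> 10,072 EUR per QALY gained.
```

Reading the output: under PP an Austrian breast-cancer patient costs
€1567 in prophylaxis drug plus FN admissions (exactly the published
total, by calibration) and avoids 0.156 FN events relative to no
prophylaxis; SP costs €980 and avoids 0.047. The €587 incremental cost
buys 0.058 QALYs — mostly through averted FN deaths — giving roughly
€10,000 per QALY, far below the €30,000 willingness-to-pay threshold
conventionally cited for Europe. The other scripts in `examples/` cover
cost calibration, the tornado analysis, the PSA/CEAC, and the
microsimulation cross-check; the same operations are available from the
shell via the `gcsfcea` command (`run`, `owsa`, `psa`, `calibrate`,
`fixtures`).

## Layout

| Module | Responsibility |
| --- | --- |
| `gcsfcea.params` | typed parameters, scenario JSON/YAML I/O, PSA distribution fitting |
| `gcsfcea.risk` | course-to-cycle risk calibration, history/prophylaxis effects |
| `gcsfcea.cohort` | cohort engine (both phases) + microsimulation oracle |
| `gcsfcea.cea` | ICERs, dominance, NMB, CEAC, results tables |
| `gcsfcea.sensitivity` | one-way (tornado) and probabilistic sensitivity analyses |
| `gcsfcea.calibration` | cost identification, Gompertz life tables, fixture building |
| `gcsfcea.datasets` | published inputs/results and fixture-level settings |
| `gcsfcea.cli` | thin command-line interface |

See `docs/methods.md` for the modelling assumptions, fixture choices and
known limitations.
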