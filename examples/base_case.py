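"""Base case: run one calibrated scenario and print the results table.

Loads the bundled Austria / breast-cancer / filgrastim scenario, runs the
cohort model under primary (PP), secondary (SP) and no prophylaxis, and
prints the two-strategy table: total discounted cost per patient, FN
events avoided versus no prophylaxis, life years, QALYs, and the three
incremental cost-effectiveness ratios with SP as reference.
"""

from gcsfcea import base_case_table, datasets, incremental, load_scenario, run_base_case

cfg = load_scenario(datasets.fixture_path("austria_bc_filgrastim"))
results = run_base_case(cfg)
res = incremental(results["PP"], results["SP"])

print(f"scenario: {cfg.scenario_id}   status: {res.status}")
print(base_case_table(results["PP"], results["SP"]).to_string(index=False))
print(
    f"\nPP costs {res.delta_cost:+.0f} EUR and gains {res.delta_qaly:.3f} QALYs "
    f"per patient vs SP -> {res.icer_qaly:,.0f} EUR per QALY gained."
)
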