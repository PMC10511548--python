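"""Validation: cohort expectations vs a patient-level microsimulation.

Simulates 200,000 individual patients through the identical event logic
(Bernoulli FN events, case fatality, RDI stratification, life-table death
years) and compares the sample means with the deterministic cohort
expectations.  Agreement within a few Monte-Carlo standard errors is the
package's main internal-validity check.
"""

from gcsfcea import datasets, load_scenario, run_strategy, simulate_individuals

cfg = load_scenario(datasets.fixture_path("france_nhl_filgrastim"))
cohort = run_strategy(cfg, "PP", with_avoided=False)
micro = simulate_individuals(cfg, "PP", n=200_000, seed=42)

print(f"{'outcome':<12}{'cohort':>12}{'microsim':>12}{'MC SE':>10}{'z':>7}")
for fld in ("cost", "ly", "qaly", "fn_events", "fn_deaths"):
    c = getattr(cohort, fld)
    m = getattr(micro.outcome, fld)
    se = micro.se[fld]
    z = (m - c) / se if se > 0 else 0.0
    print(f"{fld:<12}{c:>12.4f}{m:>12.4f}{se:>10.4f}{z:>7.2f}")
print("\n|z| values of order 1 indicate the two engines implement the same model.")
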