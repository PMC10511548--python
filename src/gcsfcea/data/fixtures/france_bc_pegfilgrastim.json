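{
 "clinical": {
  "baseline_fn_risk": 0.158,
  "p_low_rdi_fn": 0.488,
  "p_low_rdi_no_fn": 0.309,
  "rdi_threshold_pct": 85.0,
  "rr_gcsf": 0.25,
  "rr_history": 9.09,
  "rr_later_cycles": 0.21
 },
 "cohort": {
  "cancer": "BC",
  "cure_horizon_years": 20,
  "cycle_length_days": 21.0,
  "entry_age": 50.0,
  "n_cycles": 6,
  "sex_mix": 1.0
 },
 "costs": {
  "agent": "pegfilgrastim",
  "doses_per_cycle": 5,
  "drug_unit_price": 349.46573238909644,
  "fn_hospitalisation_cost": 6912.80183210403,
  "los_days": 8.0,
  "patient_weight_kg": 70.0
 },
 "country": "France",
 "discount_rate_costs": 0.025,
 "discount_rate_effects": 0.025,
 "half_cycle": "mid",
 "life_table": {
  "gompertz": {
   "a": 2.1e-05,
   "b": 0.095,
   "male_factor": 1.9,
   "terminal_age": 110
  }
 },
 "mortality": {
  "cancer_annual_mortality": 0.03,
  "fn_case_fatality": 0.056,
  "hr_low_rdi": 1.002
 },
 "provenance": {
  "clinical.baseline_fn_risk": "published",
  "clinical.p_low_rdi_fn": "published",
  "clinical.p_low_rdi_no_fn": "published",
  "clinical.rdi_threshold_pct": "published",
  "clinical.rr_gcsf": "published",
  "clinical.rr_history": "published",
  "clinical.rr_later_cycles": "published",
  "cohort.entry_age": "fixture",
  "cohort.sex_mix": "fixture",
  "costs.doses_per_cycle": "fixture",
  "costs.drug_unit_price": "calibrated",
  "costs.fn_hospitalisation_cost": "calibrated",
  "costs.los_days": "fixture",
  "costs.patient_weight_kg": "fixture",
  "discount_rate_costs": "fixture",
  "discount_rate_effects": "fixture",
  "life_table": "fixture",
  "mortality.cancer_annual_mortality": "published",
  "mortality.fn_case_fatality": "published",
  "mortality.hr_low_rdi": "published",
  "utilities.u_chemo": "published",
  "utilities.u_fn_hosp": "published",
  "utilities.u_post_later": "published",
  "utilities.u_post_year1": "published"
 },
 "psa_iterations": 1000,
 "rr_scale": "probability",
 "scenario_id": "france_bc_pegfilgrastim",
 "seed": 20230,
 "uncertainty": [
  {
   "base": 0.21,
   "family": "lognormal",
   "high": 0.29,
   "low": 0.16,
   "name": "clinical.rr_later_cycles"
  },
  {
   "base": 9.09,
   "family": "lognormal",
   "high": 13.35,
   "low": 6.19,
   "name": "clinical.rr_history"
  },
  {
   "base": 0.33,
   "family": "beta",
   "high": 0.4,
   "low": 0.27,
   "name": "utilities.u_fn_hosp"
  },
  {
   "base": 0.158,
   "family": "beta",
   "high": 0.2,
   "low": 0.1,
   "name": "clinical.baseline_fn_risk"
  },
  {
   "base": 0.309,
   "family": "beta",
   "high": 0.34,
   "low": 0.278,
   "name": "clinical.p_low_rdi_no_fn"
  },
  {
   "base": 0.488,
   "family": "beta",
   "high": 0.649,
   "low": 0.371,
   "name": "clinical.p_low_rdi_fn"
  },
  {
   "base": 0.55,
   "family": "beta",
   "high": 0.61,
   "low": 0.5,
   "name": "utilities.u_chemo"
  },
  {
   "base": 0.66,
   "family": "beta",
   "high": 0.73,
   "low": 0.59,
   "name": "utilities.u_post_year1"
  },
  {
   "base": 0.86,
   "family": "beta",
   "high": 0.95,
   "low": 0.77,
   "name": "utilities.u_post_later"
  },
  {
   "base": 0.03,
   "family": "beta",
   "high": 0.033,
   "low": 0.027,
   "name": "mortality.cancer_annual_mortality"
  },
  {
   "base": 0.056,
   "family": "beta",
   "high": 0.063,
   "low": 0.048,
   "name": "mortality.fn_case_fatality"
  },
  {
   "base": 1.002,
   "family": "lognormal",
   "high": 1.527,
   "low": 0.657,
   "name": "mortality.hr_low_rdi"
  },
  {
   "base": 0.25,
   "family": "lognormal",
   "high": 0.33928571428571425,
   "low": 0.17857142857142858,
   "name": "clinical.rr_gcsf"
  },
  {
   "base": 349.46573238909644,
   "family": "lognormal",
   "high": 419.35887886691575,
   "low": 279.57258591127714,
   "name": "costs.drug_unit_price"
  },
  {
   "base": 6912.80183210403,
   "family": "lognormal",
   "high": 8295.362198524836,
   "low": 5530.241465683224,
   "name": "costs.fn_hospitalisation_cost"
  },
  {
   "base": 8.0,
   "family": "lognormal",
   "high": 11.0,
   "low": 5.0,
   "name": "costs.los_days"
  },
  {
   "base": 70.0,
   "family": "lognormal",
   "high": 90.0,
   "low": 60.0,
   "name": "costs.patient_weight_kg"
  },
  {
   "base": 0.025,
   "family": "fixed",
   "high": 0.05,
   "low": 0.0,
   "name": "discount_rate"
  }
 ],
 "utilities": {
  "u_chemo": 0.55,
  "u_fn_hosp": 0.33,
  "u_post_later": 0.86,
  "u_post_year1": 0.66
 },
 "wtp_grid": [
  0.0,
  5000.0,
  10000.0,
  15000.0,
  20000.0,
  25000.0,
  30000.0,
  35000.0,
  40000.0,
  45000.0,
  50000.0,
  55000.0,
  60000.0,
  65000.0,
  70000.0,
  75000.0,
  80000.0,
  85000.0,
  90000.0,
  95000.0,
  100000.0
 ]
}
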