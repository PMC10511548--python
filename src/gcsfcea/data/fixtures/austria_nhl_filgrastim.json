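{
 "clinical": {
  "baseline_fn_risk": 0.18,
  "p_low_rdi_fn": 0.706,
  "p_low_rdi_no_fn": 0.408,
  "rdi_threshold_pct": 90.0,
  "rr_gcsf": 0.42,
  "rr_history": 9.09,
  "rr_later_cycles": 0.21
 },
 "cohort": {
  "cancer": "NHL",
  "cure_horizon_years": 20,
  "cycle_length_days": 21.0,
  "entry_age": 62.0,
  "n_cycles": 6,
  "sex_mix": 0.45
 },
 "costs": {
  "agent": "filgrastim",
  "doses_per_cycle": 5,
  "drug_unit_price": 29.895202911277806,
  "fn_hospitalisation_cost": 7513.826318614911,
  "los_days": 8.0,
  "patient_weight_kg": 70.0
 },
 "country": "Austria",
 "discount_rate_costs": 0.05,
 "discount_rate_effects": 0.05,
 "half_cycle": "mid",
 "life_table": {
  "gompertz": {
   "a": 2.4e-05,
   "b": 0.095,
   "male_factor": 1.7,
   "terminal_age": 110
  }
 },
 "mortality": {
  "cancer_annual_mortality": 0.0652,
  "fn_case_fatality": 0.058,
  "hr_low_rdi": 2.08
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
 "scenario_id": "austria_nhl_filgrastim",
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
   "base": 0.18,
   "family": "beta",
   "high": 0.2,
   "low": 0.1,
   "name": "clinical.baseline_fn_risk"
  },
  {
   "base": 0.408,
   "family": "beta",
   "high": 0.449,
   "low": 0.367,
   "name": "clinical.p_low_rdi_no_fn"
  },
  {
   "base": 0.706,
   "family": "beta",
   "high": 0.777,
   "low": 0.635,
   "name": "clinical.p_low_rdi_fn"
  },
  {
   "base": 0.61,
   "family": "beta",
   "high": 0.73,
   "low": 0.49,
   "name": "utilities.u_chemo"
  },
  {
   "base": 0.79,
   "family": "beta",
   "high": 0.92,
   "low": 0.62,
   "name": "utilities.u_post_year1"
  },
  {
   "base": 0.89,
   "family": "beta",
   "high": 0.96,
   "low": 0.79,
   "name": "utilities.u_post_later"
  },
  {
   "base": 0.0652,
   "family": "beta",
   "high": 0.0717,
   "low": 0.0587,
   "name": "mortality.cancer_annual_mortality"
  },
  {
   "base": 0.058,
   "family": "beta",
   "high": 0.089,
   "low": 0.0,
   "name": "mortality.fn_case_fatality"
  },
  {
   "base": 2.08,
   "family": "lognormal",
   "high": 3.7,
   "low": 1.19,
   "name": "mortality.hr_low_rdi"
  },
  {
   "base": 0.42,
   "family": "lognormal",
   "high": 0.57,
   "low": 0.3,
   "name": "clinical.rr_gcsf"
  },
  {
   "base": 29.895202911277806,
   "family": "lognormal",
   "high": 35.87424349353336,
   "low": 23.916162329022246,
   "name": "costs.drug_unit_price"
  },
  {
   "base": 7513.826318614911,
   "family": "lognormal",
   "high": 9016.591582337893,
   "low": 6011.0610548919285,
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
   "base": 0.05,
   "family": "fixed",
   "high": 0.05,
   "low": 0.0,
   "name": "discount_rate"
  }
 ],
 "utilities": {
  "u_chemo": 0.61,
  "u_fn_hosp": 0.33,
  "u_post_later": 0.89,
  "u_post_year1": 0.79
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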