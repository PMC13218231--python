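# ckdsim frozen parameter fixture
#
# Published quantities (Danish registry aggregates, trial-anchored treatment
# assumptions, tariff-based unit costs) carry their printed values.  Where
# the sources publish no number (progression coefficients, event-rate
# coefficients, the mortality relative-risk grid, utilities, event-level
# costs), the entries below are the package's documented assumptions,
# calibrated so that the base case reproduces the published 10-year kidney
# failure risk and mortality (see docs/methods.md, "Calibration").
version: "2026.1"

prevalent_cohort:
  population_label: prevalent
  n_patients: 10000        # overridden by the scenario's microsim scale
  mean_age: 76
  pct_male: 0.45
  mean_egfr: 56
  mean_uacr: 75
  mean_hba1c: 5.9
  mean_bmi: 28.5
  mean_cholesterol: 174
  mean_sbp: 132
  stage_distribution: {G3a: 0.679, G3b: 0.238, G4: 0.066, G5: 0.017}
  comorbidity_prevalence: {diabetes: 0.192, cvd: 0.267, hypertension: 0.476, chf: 0.101}
  dispersion: {age_sd: 10.0, bmi_sd: 5.0, sbp_sd: 15.0, cholesterol_sd: 35.0, hba1c_sd: 0.8, uacr_sigma: 0.9}

incident_cohort:
  population_label: incident
  n_patients: 1000
  mean_age: 74
  pct_male: 0.44
  mean_egfr: 54
  mean_uacr: 21
  mean_hba1c: 5.9
  mean_bmi: 28.5
  mean_cholesterol: 174
  mean_sbp: 132
  stage_distribution: {G3a: 0.758, G3b: 0.187, G4: 0.048, G5: 0.007}
  comorbidity_prevalence: {diabetes: 0.138, cvd: 0.235, hypertension: 0.494, chf: 0.085}
  dispersion: {age_sd: 10.0, bmi_sd: 5.0, sbp_sd: 15.0, cholesterol_sd: 35.0, hba1c_sd: 0.8, uacr_sigma: 0.9}

progression:
  baseline_egfr_slope: -2.148
  slope_sd: 0.8
  slope_modifiers:
    age_per_decade: -0.15
    diabetes: -0.6
    hypertension: -0.2
    sbp_per_10mmhg: -0.15
    hba1c_per_unit: -0.2
    uacr_a2: -0.4
    uacr_a3: -1.2
    ref_age: 75.0
    ref_sbp: 132.0
    ref_hba1c: 5.9
  uacr_annual_growth: 0.04
  sbp_annual_drift: 0.3
  hba1c_annual_drift: 0.01
  egfr_floor: 2.0
  uacr_cap: 5000.0

treatment:
  chronic_slope_multiplier: 0.62
  acute_egfr_dip: 2.0
  uacr_relative_reduction: 0.30
  sbp_reduction: 2.6
  hba1c_reduction: 0.1
  annual_discontinuation_probability: 0.05
  adverse_event_rates: {treatment_adverse_event: 0.01}
  effect_scale: 1.0

mortality:
  # Gompertz-shaped age baseline (hazard/year), tabulated every 5 years
  age_grid:    [40, 45, 50, 55, 60, 65, 70, 75, 80, 85, 90, 95, 100, 105, 110]
  baseline_annual_hazard: [0.000859, 0.001313, 0.002010, 0.003073, 0.004701,
                           0.007192, 0.011000, 0.016825, 0.025736, 0.039369,
                           0.060213, 0.092102, 0.140877, 0.215479, 0.329604]
  # rows G1..G5, columns A1..A3; monotone in both directions
  relative_risk_grid:
    - [1.00, 1.10, 1.25]
    - [1.05, 1.15, 1.35]
    - [1.15, 1.30, 1.55]
    - [1.35, 1.50, 1.80]
    - [1.60, 1.80, 2.10]
    - [1.90, 2.10, 2.50]
  calibration_multiplier: 1.638

events:
  ref_age: 75.0
  ref_sbp: 132.0
  ref_hba1c: 5.9
  models:
    mace:
      intercept: -4.70
      age_per_year: 0.02
      sbp_per_10mmhg: 0.10
      hba1c_per_unit: 0.05
      g_offsets: [-0.10, -0.05, 0.0, 0.15, 0.35, 0.60]
      diabetes: 0.30
      cvd: 0.50
      chf: 0.20
    new_hf:
      intercept: -5.50
      age_per_year: 0.02
      sbp_per_10mmhg: 0.15
      hba1c_per_unit: 0.08
      g_offsets: [-0.10, -0.05, 0.0, 0.15, 0.35, 0.55]
      diabetes: 0.30
      cvd: 0.40
    cvd_hosp:
      intercept: -3.70
      age_per_year: 0.015
      sbp_per_10mmhg: 0.12
      hba1c_per_unit: 0.05
      g_offsets: [-0.10, -0.05, 0.0, 0.15, 0.30, 0.50]
      cvd: 0.50
      chf: 0.40
    aki:
      intercept: -4.00
      age_per_year: 0.02
      g_offsets: [0.0, 0.0, 0.0, 0.30, 0.70, 1.10]
      diabetes: 0.20
    anemia:
      intercept: -4.00
      g_offsets: [0.0, 0.0, 0.0, 0.40, 0.90, 1.30]
    mbd:
      intercept: -4.40
      g_offsets: [0.0, 0.0, 0.0, 0.40, 0.90, 1.30]
    new_diabetes:
      intercept: -4.80
      hba1c_per_unit: 0.60
    new_hypertension:
      intercept: -3.50
      sbp_per_10mmhg: 0.40
    infection:
      intercept: -3.20
      age_per_year: 0.02
      g_offsets: [0.0, 0.0, 0.0, 0.20, 0.40, 0.70]
      diabetes: 0.20
    other_ae:
      intercept: -4.60
      g_offsets: [0.0, 0.0, 0.0, 0.10, 0.25, 0.45]
      diabetes: 0.40

krt:
  initiation_split: {hemodialysis: 0.56, peritoneal_dialysis: 0.21, transplant: 0.23}
  transitions:
    hemodialysis: {peritoneal_dialysis: 0.02, transplant: 0.035, dead: 0.16}
    peritoneal_dialysis: {hemodialysis: 0.12, transplant: 0.05, dead: 0.11}
    transplant: {hemodialysis: 0.03, dead: 0.03}
  initiation_probability: 0.35
  allow_graft_failure: true

costs:
  stage_costs:
    g1: {low: 600, high: 600}
    g2: {low: 900, high: 900}
    g3a: {low: 1242, high: 2098}
    g3b: {low: 1456, high: 2327}
    g4: {low: 1859, high: 3062}
    g5: {low: 2509, high: 5572}
  hemodialysis_annual: 63455
  peritoneal_dialysis: {low: 36869, high: 42572}
  transplant: {low: 37481, high: 44603}
  immunosuppression_annual: 10678
  sglt2i_annual: 567
  soc_annual: 13
  cvd_event_costs:
    mace: {acute: 9000, followup_annual: 1800}
    new_hf: {acute: 7500, followup_annual: 1500}
    cvd_hosp: {acute: 4800, followup_annual: 300}
  other_event_costs:
    aki: {amount: 4200, timing: per_event}
    anemia: {amount: 1100, timing: annual}
    mbd: {amount: 900, timing: annual}
    new_diabetes: {amount: 1200, timing: first_year}
    new_hypertension: {amount: 350, timing: first_year}
    infection: {amount: 2500, timing: per_event}
    other_ae: {amount: 800, timing: per_event}
    treatment_adverse_event: {amount: 150, timing: per_event}
  exchange_rate_dkk_per_eur: 7.46
  price_year: 2024
  price_multiplier: 1.0

utilities:
  g_utilities: [0.87, 0.85, 0.82, 0.80, 0.76, 0.70]
  hemodialysis: 0.57
  peritoneal_dialysis: 0.62
  transplant: 0.73
  age_grid:    [18, 40, 50, 60, 70, 80, 90, 110]
  age_utility: [0.93, 0.92, 0.90, 0.87, 0.84, 0.79, 0.73, 0.62]
  event_disutilities:
    mace: 0.10
    new_hf: 0.08
    cvd_hosp: 0.03
    aki: 0.04
    anemia: 0.02
    mbd: 0.02
    new_diabetes: 0.02
    new_hypertension: 0.01
    infection: 0.02
    other_ae: 0.01
    treatment_adverse_event: 0.005

scenario:
  uptake: 0.15
  start_year: 2026
  horizon_years: 10
  initial_total_ckd: 251946
  annual_incidence: 27816
  eligibility_fraction: 0.2675
  microsim_scale: 0.1668
  seed: 1
  effect_scale: 1.0
  price_multiplier: 1.0
  krt_capacity_band: [2500, 2700]
  current_krt_patients: 2600
  krt_baseline_eligible_share: 0.70
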