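# Default model inputs: decision-tree economic evaluation of test-treat
# strategies for women with refractory overactive bladder / urgency-
# predominant mixed incontinence (UK NHS perspective, 2012-13 prices).
#
# Cure probabilities, pathway probabilities, unit costs and utilities are
# the published table values with their Beta/Gamma parameterisations.
# The accuracy / prevalence / clinical-history blocks are SYNTHETIC
# stand-ins: counts taken from one frozen cohort (n = 209, seed 101) of
# the package's own generator, because the primary study's individual
# data are not deposited. Override them if study estimates are available.

schema_version: 1
price_year: "2012-13"

economics:
  discount_rate: 0.035
  horizon_years: 5
  psa_iterations: 10000
  incidence_per_year: 54000
  research_horizon_years: 10
  wtp_grid_success: {start: 0, stop: 100000, step: 500}
  wtp_grid_qaly: {start: 0, stop: 50000, step: 250}

# P(subjective cure | treatment, true condition). "expert" rows were
# elicited (most likely / lowest / highest read as mean and 95% CI) and
# are the targets of the expert_low / expert_high scenarios.
cure_probabilities:
  botulinum:
    detrusor_overactivity: {dist: beta, alpha: 50, beta: 38}
    mixed_incontinence: {dist: beta, alpha: 13.42, beta: 27.36, expert: true, ci: [0.200, 0.483]}
    # Also the proxy for any intervention delivered after misdiagnosis to
    # women with a normal bladder, low compliance only, or voiding
    # dysfunction only (most conservative elicited estimate).
    stress_incontinence: {dist: beta, alpha: 4.32, beta: 25.86, expert: true, ci: [0.133, 0.375]}
  neurostimulation:
    detrusor_overactivity: {dist: beta, alpha: 245, beta: 159}
    stress_or_mixed: {dist: beta, alpha: 12.36, beta: 27, expert: true, ci: [0.283, 0.567]}
  implanted_neurostimulator:
    detrusor_overactivity: {dist: beta, alpha: 338, beta: 163}
    stress_or_mixed: {dist: beta, alpha: 7.74, beta: 20.82, expert: true, ci: [0.233, 0.550]}
  sling:
    detrusor_overactivity: {dist: beta, alpha: 5.84, beta: 13}
    stress_incontinence: {dist: beta, alpha: 547, beta: 83}
    mixed_incontinence: {dist: beta, alpha: 1050, beta: 837}
  colposuspension:
    detrusor_overactivity: {dist: beta, alpha: 5.95, beta: 30.56, expert: true, ci: [0.153, 0.386]}
    stress_incontinence: {dist: beta, alpha: 100, beta: 45}
    mixed_incontinence: {dist: beta, alpha: 40, beta: 42}

pathway_probabilities:
  choose_botox_prior_to_sling: {dist: beta, alpha: 5.74, beta: 12.53}
  choose_botox_over_neurostim: {dist: beta, alpha: 6, beta: 2}
  voiding_difficulty_after_botox: {dist: beta, alpha: 10, beta: 106}
  require_implant_after_pne: {dist: beta, alpha: 11.23, beta: 5.53}
  implant_revision_lt2y: {dist: beta, alpha: 36, beta: 366}
  implant_revision_ge2y: {dist: beta, alpha: 282, beta: 573}
  implant_maintenance_ge2y: {dist: beta, alpha: 42, beta: 237}
  implant_removal: {dist: beta, alpha: 22, beta: 184}

# Unit costs (GBP, 2012-13). Rows without a CI were fitted with
# dispersion equal to the mean (shape 1).
costs:
  urodynamics: {dist: gamma, shape: 40.65, scale: 9.86}
  ultrasonography: {dist: gamma, shape: 1.00, scale: 51.07}
  botulinum_injection: {dist: gamma, shape: 100.67, scale: 9.06}
  neurostimulation_course: {dist: gamma, shape: 30.81, scale: 72.08}
  sling: {dist: gamma, shape: 31.93, scale: 122.69}
  pne: {dist: gamma, shape: 258.88, scale: 4.49}
  implant: {dist: gamma, shape: 57.14, scale: 114.28}
  implant_followup: {dist: gamma, shape: 32.09, scale: 129.65}
  colposuspension: {dist: gamma, shape: 31.93, scale: 122.69}
  self_cath_training: {dist: gamma, shape: 1.00, scale: 84.00}

utilities:
  detrusor_overactivity: {dist: beta, alpha: 8.96, beta: 5.98}
  stress_incontinence: {dist: beta, alpha: 18.92, beta: 9.75}
  mixed_incontinence: {dist: beta, alpha: 49.12, beta: 19.29}
  normal_bladder: {dist: beta, alpha: 22.13, beta: 11.61}
  low_compliance_or_voiding_dysfunction: {dist: beta, alpha: 11.76, beta: 4.05}
  cured_no_side_effects: {dist: beta, alpha: 10.69, beta: 0.93}
  cured_with_side_effects: {dist: beta, alpha: 304, beta: 45.43}

# SYNTHETIC: 2x2 counts of the BWT index test (>= 5 mm) against
# urodynamics, and clinical-history classification per true diagnosis,
# from the frozen generator cohort.
accuracy:
  synthetic: true
  bwt_threshold_mm: 5.0
  reference_positive_includes_mixed: false
  bwt_sensitivity: {dist: beta, alpha: 28, beta: 60}
  bwt_specificity: {dist: beta, alpha: 98, beta: 23}
  # Urodynamics is the reference standard; 1.0 means it classifies DO
  # perfectly. Lowered by the uds_accuracy_low_plus_diary scenario.
  uds_sensitivity: {dist: point, value: 1.0}
  history_mixed_given:
    detrusor_overactivity: {dist: beta, alpha: 37, beta: 51}
    stress_incontinence: {dist: beta, alpha: 19, beta: 10}
    mixed_incontinence: {dist: beta, alpha: 26, beta: 6}
    normal_bladder: {dist: beta, alpha: 14, beta: 19}
    low_compliance_only: {dist: beta, alpha: 8, beta: 4}
    voiding_dysfunction_only: {dist: beta, alpha: 10, beta: 5}

# SYNTHETIC: urodynamic diagnosis mix (counts from the frozen cohort).
prevalence:
  synthetic: true
  dist: dirichlet
  concentrations:
    detrusor_overactivity: 88
    stress_incontinence: 29
    mixed_incontinence: 32
    normal_bladder: 33
    low_compliance_only: 12
    voiding_dysfunction_only: 15

# Up to three injections at yearly intervals; drop-out after injections
# 1 and 2 gives per-injection uptake 1.00 / 0.80 / 0.736. The cure
# contributions split the overall course cure probability by injection.
botulinum_course:
  dropout_after_1: 0.20
  dropout_after_2: 0.08
  cure_contributions: [0.34, 0.52, 0.14]

model_options:
  # A maximum of two diagnostic tests: one at entry (where the strategy
  # tests) and, in conditional strategies, the strategy's test for
  # untested women whose first treatment cycle fails.
  second_test_enabled: true

scenario_settings:
  uds_cost_low_mean: 173          # weighted average of total HRGs
  cured_utility_low: 0.84         # EQ-5D for low symptom bother
  uds_sensitivity_low: 0.90       # synthetic: conventional urodynamics missing DO
  # SYNTHETIC: history complemented by urinary diaries (better concordance)
  history_with_diary_mixed_given:
    detrusor_overactivity: 0.25
    stress_incontinence: 0.85
    mixed_incontinence: 0.90
    normal_bladder: 0.44
    low_compliance_only: 0.50
    voiding_dysfunction_only: 0.50
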