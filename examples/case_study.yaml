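# First-in-human dose-optimization protocol: 8 planned dose levels,
# target DLT rate 30%, cohorts of three, maximum 27 patients with a
# per-dose cap of 12, accelerated single-patient titration until the
# first toxicity or dose level 5.  ICE strategies follow the case-study
# assignments (toxicity discontinuation and death as composite failures,
# additional therapy while-on-treatment, ADA/dose-switch treatment policy,
# surgery handled by cause).
design:
  n_doses: 8
  cohort_size: 3
  max_n: 27
  per_dose_cap: 12
  start_dose: 1
  mode: utility_boin12
  policy: deterministic_max_utility
  accelerated_titration: true
  titration_trigger_dose: 5
  phi_t: 0.35          # toxicity upper limit, slightly above the 30% target
  phi_e: 0.25          # efficacy lower limit (phase-II-style target rate)
  delta_t: 0.95
  delta_e: 0.95
  prior: vague
  dlt_window_days: 28
  boin:                # toxicity-interval boundaries for the BOIN comparison
    phi: 0.30

utility:
  scores: [0, 10, 60, 100]   # psi_1..psi_4 on the elicitation scale

strategies:
  per_ice_strategy:
    discontinuation_toxicity: composite
    death: composite
    additional_therapy: while_on_treatment
    progression_discontinuation: composite
    ada_occurrence: treatment_policy
    dose_switch: treatment_policy
    surgery_clinician_choice: while_on_treatment
    surgery_treatment_failure: composite
    surgery_external: hypothetical
    nonadherence: treatment_policy
  composite_toxicity_types: [death, discontinuation_toxicity]

# Simulation truth emulating a benign-toxicity compound whose activity
# rises and then plateaus over a broad dose range (bell/plateau shape);
# category order is (tox only, neither, both, efficacy only).
scenario:
  category_probs:
    - [0.019, 0.931, 0.001, 0.049]   # pe=0.05, pt=0.02
    - [0.027, 0.873, 0.003, 0.097]   # pe=0.10, pt=0.03
    - [0.028, 0.672, 0.012, 0.288]   # pe=0.30, pt=0.04
    - [0.020, 0.380, 0.030, 0.570]   # pe=0.60, pt=0.05
    - [0.026, 0.414, 0.034, 0.526]   # pe=0.56, pt=0.06
    - [0.036, 0.414, 0.044, 0.506]   # pe=0.55, pt=0.08
    - [0.045, 0.405, 0.055, 0.495]   # pe=0.55, pt=0.10
    - [0.060, 0.340, 0.090, 0.510]   # pe=0.60, pt=0.15
  ice_probs:
    discontinuation_toxicity: 0.08
    additional_therapy: 0.05
    death: 0.01
  ice_time_mean:
    discontinuation_toxicity: 20
    additional_therapy: 35
    death: 25
  followup_prob: 0.6
  assess_window: 56
  dlt_window: 28
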