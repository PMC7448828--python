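# Base-case model inputs (2019 USD), one block per input-table section.
# Distribution families drive the probabilistic sensitivity analysis;
# `range` entries are the published low/high bounds, also used by the
# one-way (tornado) sensitivity analysis.

settings:
  cycle_length: 0.25
  discount_rate: 0.03
  cohort_size: 1000
  psa_draws: 2000
  max_age: 110
  wtp_grid: [0, 25000, 50000, 100000, 150000, 200000]
  seed: 20200825
  accrue_acute_qalys: true
  half_cycle_correction: false
  extinction_tol: 1.0e-6

transitions:
  recurrence_prob:
    base: 0.013
    dist: {family: beta, alpha: 13.0, beta: 986.0}
  post_recurrence_death:
    # published as Beta(94.9, 5.1) on the survive-recurrence side (mean 0.949)
    base: 0.0513
    dist: {family: beta, alpha: 5.1, beta: 94.9}
  death_hr:
    base: [1.0, 1.0, 1.11, 1.27, 1.71, 2.37]
    se: [0.076, 0.46, 0.46, 0.46, 0.46, 0.46]
    # mRS 0/1 are the reference category (HR 1); held fixed in PSA
    sampled: [false, false, true, true, true, true]

costs:
  imaging:
    ct:       {base: 198,  dist: {family: beta_pert, range: [168, 228]}}
    cta:      {base: 774,  dist: {family: beta_pert, range: [658, 890]}}
    mri:      {base: 625,  dist: {family: beta_pert, range: [531, 718]}}
    mra:      {base: 1023, dist: {family: beta_pert, range: [870, 1176]}}
    ctp:      {base: 836,  dist: {family: beta_pert, range: [711, 961]}}
    software: {base: 89,   dist: {family: beta_pert, range: [44, 520]}}
  freq_cta_vs_mra: {base: 0.5, dist: {family: uniform, low: 0.0, high: 1.0, range: [0.0, 1.0]}}
  freq_ctp_vs_mri: {base: 0.5, dist: {family: uniform, low: 0.0, high: 1.0, range: [0.0, 1.0]}}
  tpa_cost:     {base: 8004,  dist: {family: beta_pert, range: [6403, 9605]}}
  mt_procedure: {base: 15836, dist: {family: beta_pert, range: [5270, 26401]}}
  mt_physician: {base: 2749,  dist: {family: beta_pert, range: [1262, 4236]}}
  acute_90d:
    mrs0_2: {base: 14382, dist: {family: beta_pert, range: [14210, 14554]}}
    mrs3_5: {base: 17879, dist: {family: beta_pert, range: [17660, 18097]}}
    death:  {base: 23498, dist: {family: beta_pert, range: [22614, 24382]}}
  longterm_3mo:
    mrs0: {base: 2836,  dist: {family: beta_pert, range: [2269, 3403]}}
    mrs1: {base: 2741,  dist: {family: beta_pert, range: [2336, 3504]}}
    mrs2: {base: 3378,  dist: {family: beta_pert, range: [2703, 4054]}}
    mrs3: {base: 5801,  dist: {family: beta_pert, range: [4641, 6961]}}
    mrs4: {base: 11742, dist: {family: beta_pert, range: [9393, 14090]}}
    mrs5: {base: 17262, dist: {family: beta_pert, range: [13809, 20714]}}

utilities:
  mrs0: {base: 0.85, dist: {family: beta, range: [0.80, 1.00]}}
  mrs1: {base: 0.80, dist: {family: beta, range: [0.80, 0.95]}}
  mrs2: {base: 0.70, dist: {family: beta, range: [0.68, 0.90]}}
  mrs3: {base: 0.51, dist: {family: beta, range: [0.45, 0.65]}}
  mrs4: {base: 0.30, dist: {family: beta, range: [0.10, 0.40]}}
  mrs5: {base: 0.15, dist: {family: beta, range: [0.00, 0.32]}}

# Composite low/high 90-day efficacy vectors for the thrombectomy arm,
# used as a single grouped entry in the one-way sensitivity analysis.
efficacy_scenarios:
  mt_low_efficacy:  [0.07, 0.20, 0.15, 0.14, 0.145, 0.115, 0.18]
  mt_high_efficacy: [0.10, 0.23, 0.18, 0.13, 0.12, 0.09, 0.15]

# Per-arm resource-use context the efficacy tables do not carry.
# IV-tPA frequencies are SYNTHETIC defaults (trial-report supplement values
# are not reproduced here); male fractions are the published proportions.
trial_arms:
  DAWN:
    MT_SMC: {tpa_frequency: 0.05, male_fraction: 0.393}
    SMC:    {tpa_frequency: 0.13, male_fraction: 0.515}
  DEFUSE3:
    MT_SMC: {tpa_frequency: 0.10, male_fraction: 0.500}
    SMC:    {tpa_frequency: 0.11, male_fraction: 0.489}
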