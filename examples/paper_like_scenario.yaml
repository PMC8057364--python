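n_households: 387
seed: 20180615
income_lognormal:
- 8.668
- 0.592
engel_params:
- 0.4
- 0.07
- 0.06
consumption_rate: 0.85
consumption_noise_sd: 1500.0
household_size_probs:
- 0.05
- 0.12
- 0.22
- 0.25
- 0.16
- 0.1
- 0.05
- 0.03
- 0.01
- 0.01
diagnosis_probs:
  schizophrenia: 0.35
  hyperactive: 0.3
  anxiety: 0.12
  other: 0.23
patient_male_prob: 0.74
patient_employed_prob: 0.25
caregiver_female_prob: 0.86
caregiver_single_prob: 0.928
oop_components:
  consultation:
    p_intercept: 0.8
    p_coefs: {}
    amount_median: 300.0
    amount_coefs:
      male: 0.25
      employed: -0.3
    amount_sdlog: 0.6
  hospitalization:
    p_intercept: -1.3
    p_coefs:
      schizophrenia: 0.8
      hyperactive: 0.4
      anxiety: -2.0
    amount_median: 1500.0
    amount_coefs:
      schizophrenia: 0.3
    amount_sdlog: 0.6
  medicines:
    p_intercept: 1.4
    p_coefs:
      schizophrenia: 0.6
      anxiety: -1.2
    amount_median: 700.0
    amount_coefs:
      schizophrenia: 0.4
    amount_sdlog: 0.6
  diagnostics:
    p_intercept: -0.6
    p_coefs:
      employed: -0.3
    amount_median: 400.0
    amount_coefs: {}
    amount_sdlog: 0.7
  transport:
    p_intercept: 1.2
    p_coefs:
      size_c: 0.1
    amount_median: 250.0
    amount_coefs:
      male: 0.2
      size_c: 0.05
      missed_days: 0.05
    amount_sdlog: 0.6
oop_scale: 0.3672
target_incidence: 0.35
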