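unit_costs:
  premm5_calc: 3.58
  ihc4: 30.36
  ihc2: 15.18
  msi: 36.63
  meth_s2: 22.84
  meth_s3: 32.65
  ngs_consent: 13.64
  ngs: 236.35
  counsel_post_proband: 133.15
  counsel_pre_relative: 171.73
  predictive_test_relative: 166.32
  counsel_post_relative: 133.15
  labour_oncost_factor: 2.08
  counsel_first_visit_alt: 428.0
  counsel_followup_alt: 403.0
  nhs_reference_delta: 60.0
markov:
  incidence:
    sporadic:
    - - 0
      - 0.0
    - - 30
      - 0.0002
    - - 50
      - 0.001
    - - 60
      - 0.002
    - - 70
      - 0.003
    path_MLH1:
    - - 0
      - 0.0
    - - 25
      - 0.008
    - - 40
      - 0.015
    - - 50
      - 0.02
    - - 70
      - 0.015
    path_MSH2:
    - - 0
      - 0.0
    - - 25
      - 0.006
    - - 40
      - 0.012
    - - 50
      - 0.016
    - - 70
      - 0.012
    path_MSH6:
    - - 0
      - 0.0
    - - 30
      - 0.002
    - - 40
      - 0.005
    - - 50
      - 0.008
    - - 70
      - 0.007
    path_PMS2:
    - - 0
      - 0.0
    - - 35
      - 0.001
    - - 50
      - 0.003
    - - 60
      - 0.004
    - - 70
      - 0.004
  male_incidence_factor: 1.2
  surveillance_hr: 0.387
  stage_dist_surv:
  - 0.6666666666666667
  - 0.12121212121212123
  - 0.12121212121212123
  - 0.09090909090909091
  stage_dist_nosurv:
  - 0.19047619047619047
  - 0.4920634920634921
  - 0.20634920634920637
  - 0.1111111111111111
  stage_mortality:
  - 0.02
  - 0.06
  - 0.15
  - 0.45
  excess_mortality_years: 5
  background_mortality:
    a: 1.0e-05
    b: 0.105
    male_factor: 1.5
  utility_profile:
    base: 0.95
    decline_per_year: 0.0022
    floor: 0.3
  stage4_utility_multiplier: 0.789
  colonoscopy_cost: 583.0
  colonoscopy_interval: 2
  crc_cost:
    0:
    - 6500.0
    - 10500.0
    - 14000.0
    - 12500.0
    40:
    - 6800.0
    - 11000.0
    - 14490.0
    - 13000.0
    50:
    - 6400.0
    - 10400.0
    - 13800.0
    - 12000.0
    60:
    - 5900.0
    - 9600.0
    - 12600.0
    - 10400.0
    70:
    - 4900.0
    - 8000.0
    - 10300.0
    - 7400.0
    80:
    - 3400.0
    - 5400.0
    - 6900.0
    - 807.0
  discount_rate: 0.035
  max_age: 100
  half_cycle_correction: false
cascade:
  relatives_gp: 6.0
  relatives_counselled: 4.7
  relatives_tested: 3.3
  relatives_diagnosed: 1.5
  gp_visit_cost: 38.0
  quintile_ages:
  - 24.5
  - 35.7
  - 45.0
  - 53.2
  - 66.8
  sexes:
  - female
  - male
  counsel_all_tested: true
scenario:
  age_filter_under70: false
  premm5_filter: false
  two_antibody_panel: false
  msi_low_positive: false
  counselling_cost_variant: base
  premm5_missing_eligible: false
psa:
  n_iterations: 200
  seed: 0
  cv: 0.15
  resample: true
targets:
  n_total: 500
  n_ls: 16
  genotype_split:
    path_MSH6: 8
    path_MSH2: 4
    path_MLH1: 2
    path_PMS2: 2
  n_ls_under70: 15
  n_sporadic_under70: 314
  n_ls_msih: 9
  n_premm5_available: 299
  n_ls_premm5_available: 13
  n_ls_premm5_high: 11
  n_sporadic_premm5_high: 153
  mean_age_ls: 54.0
  mean_age_sporadic: 63.5
seed: 0
output_dir: outputs
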