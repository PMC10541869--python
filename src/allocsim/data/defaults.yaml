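# Packaged defaults: the single source of truth for every tunable.
# Values with a citation-grade provenance (arrival/departure rates, initial
# list size, donor sample size, HLA divisor z, national threshold) are the
# framework's published defaults; everything else (synthetic-cohort marginals,
# exit-risk coefficients) is a documented stand-in for registry quantities.

seed: 0

dynamics:
  n0: 300                 # initial waiting-list size
  lambda_in: 0.7          # daily arrival rate (Poisson)
  lambda_out: 0.4         # daily departure-without-transplant rate (Poisson)
  k_in: {}                # calendar-year -> multiplier on lambda_in (missing year = 1)
  k_out: {}               # calendar-year -> multiplier on lambda_out
  reentry_prob: 0.0       # daily probability a departed candidate rejoins the pool
  strata_targets: null    # optional {variable: {category: freq}} for stratified sampling
  start_date: null        # simulation clock start; null = first donor date

score:
  national_threshold: 54000000   # scores strictly above route to the national tier
  level_base: 10000000           # score units per match level in the surrogate score

eligibility:
  mode: default           # default | corisk | irisk
  c: 40.0                 # CORisk shared percentile cut-off (%)
  s: 20.0                 # IRisk percentile bandwidth (%)

acceptance:
  z: 50.0                 # HLA scaling divisor in p_j = (1 - PRA/100)(1 - HLA/z)
  alpha2_threshold: 0.0   # slack (percentile points) in the quality-gap consideration
  alpha2_mode: percentile # percentile | raw

engine:
  process: III            # I | II | III | custom
  donor_sample_size: 800
  decision_model: null    # null = implied by process (I -> sdm0, II/III -> sdm1)
  dynamic_waitlist: null  # null = implied by process; only `custom` may set it
  rounds:                 # allocation round sequence: [tier, ABO mode]
    - [national, strict]
    - [state, strict]
    - [national, compatible]
  state_balance: false
  waiting_time_from: listing   # listing | dialysis
  replications: 1
  workers: 1

cohort:
  n_candidates: 4000
  n_donors: 1200
  start_date: 2010-01-01
  end_date: 2012-12-31

exit_scorer:
  # Logistic-linear exit-without-transplant risk; higher score = removed first.
  coefficients:
    intercept: -3.0
    age: 0.02                    # per year
    sex_m: 0.10
    lung_disease: 0.50
    smoking: 0.30
    diabetes: 0.40
    cardiovascular_disease: 0.50
    cancer: 0.70
    pra: 0.005                   # per percentage point
    years_on_dialysis: 0.08      # per year, evaluated at the current clock date
    blood_group: {O: 0.0, A: 0.0, B: 0.0, AB: 0.0}
    state: {NSW: 0.0, ACT: 0.0, VIC: 0.0, TAS: 0.0, WA: 0.0, SA: 0.0, NT: 0.0, QLD: 0.0}

marginals:
  age_bands:                     # [low, high, probability]; age uniform within band
    - [0, 17, 0.06]
    - [18, 44, 0.34]
    - [45, 64, 0.45]
    - [65, 80, 0.15]
  sex: {F: 0.38, M: 0.62}
  blood_group: {O: 0.49, A: 0.38, B: 0.10, AB: 0.03}
  state: {NSW: 0.31, ACT: 0.02, VIC: 0.26, TAS: 0.02, WA: 0.10, SA: 0.07, NT: 0.01, QLD: 0.21}
  pra_bands:
    - [0, 10, 0.55]
    - [10, 50, 0.20]
    - [50, 80, 0.15]
    - [80, 100, 0.10]
  comorbidities:
    lung_disease: 0.08
    smoking: 0.25
    diabetes: 0.35
    cardiovascular_disease: 0.30
    cancer: 0.05
  prior_transplant_rate: 0.12
  dialysis_fraction: 0.95        # share of candidates already on dialysis at listing
  dialysis_years_mean: 2.5       # exponential mean of years on dialysis at listing
  kdri_log_mu: 0.0               # KDRI ~ lognormal(mu, sigma); 1.0 = reference donor
  kdri_log_sigma: 0.3
  donor_age_mean: 48.0
  donor_age_sd: 16.0
  donor_age_range: [5, 80]
  hla_pools:
    A:  {A1: 0.16, A2: 0.28, A3: 0.13, A11: 0.08, A24: 0.15, A26: 0.05, A29: 0.04, A32: 0.04, A68: 0.07}
    B:  {B7: 0.12, B8: 0.11, B13: 0.04, B27: 0.05, B35: 0.12, B40: 0.10, B44: 0.14, B51: 0.08, B57: 0.05, B62: 0.19}
    DR: {DR1: 0.10, DR3: 0.12, DR4: 0.16, DR7: 0.13, DR11: 0.12, DR13: 0.12, DR15: 0.15, DR8: 0.10}
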