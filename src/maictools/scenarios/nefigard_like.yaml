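# Index-trial scenario: a 364-subject parallel-arm RCT whose baseline
# marginals equal the index trial's published baseline column (note every
# published percentage is an integer count over 364: 240 male, 275 White,
# 148 with UACR > 1.1 g/g, 239 with urinary protein > 1.8 g/day).
# SDs / log-normal sigmas and the copula correlation are assumptions of the
# generator, not published quantities.
trial_id: index
n: 364
allocation: 0.5
seed: 0
visit_months: [3, 6, 9, 12, 18, 24]
censor_month: 24
marginals:
  age: {dist: truncnorm, mean: 42.70, sd: 10.0, low: 18.0}
  male: {dist: bernoulli, p: 0.6593406593406593}
  white: {dist: bernoulli, p: 0.7554945054945055}
  egfr: {dist: truncnorm, mean: 57.87, sd: 17.0, low: 10.0}
  upcr: {dist: lognormal, mean: 1.48, sigma: 0.55}
  uacr: {dist: lognormal, threshold: 1.1, exceed_prob: 0.4065934065934066, sigma: 0.70}
  uprot24h: {dist: lognormal, threshold: 1.8, exceed_prob: 0.6565934065934066, sigma: 0.60}
correlation:
  order: [age, male, white, egfr, upcr, uacr, uprot24h]
  matrix:
    - [1.00, 0.05, 0.00, -0.35, 0.05, 0.05, 0.05]
    - [0.05, 1.00, 0.00, 0.00, 0.10, 0.10, 0.10]
    - [0.00, 0.00, 1.00, 0.00, 0.00, 0.00, 0.00]
    - [-0.35, 0.00, 0.00, 1.00, -0.20, -0.20, -0.20]
    - [0.05, 0.10, 0.00, -0.20, 1.00, 0.85, 0.80]
    - [0.05, 0.10, 0.00, -0.20, 0.85, 1.00, 0.70]
    - [0.05, 0.10, 0.00, -0.20, 0.80, 0.70, 1.00]
# 9-month active treatment course: eGFR gain on treatment, partial decline
# after withdrawal; steady decline on supportive care alone.
egfr_effects:
  active: {3: 0.5, 6: 1.8, 9: 2.7, 12: 1.8, 18: -0.5, 24: -2.5}
  control: {3: -1.0, 6: -2.0, 9: -3.0, 12: -4.2, 18: -5.5, 24: -7.0}
egfr_intercept_sd: 4.0
egfr_residual:
  sd: [5.0, 5.5, 6.0, 6.0, 6.5, 7.0]
  corr: 0.55
# log post/baseline ratio effects (negative = proteinuria reduction);
# the largest reductions occur shortly after the treatment course ends.
ratio_effects:
  upcr:
    active: {3: -0.15, 6: -0.30, 9: -0.45, 12: -0.55, 18: -0.45, 24: -0.35}
    control: {3: -0.02, 6: -0.04, 9: -0.05, 12: -0.06, 18: -0.08, 24: -0.10}
  uacr:
    active: {3: -0.20, 6: -0.38, 9: -0.55, 12: -0.65, 18: -0.50, 24: -0.40}
    control: {3: -0.02, 6: -0.05, 9: -0.06, 12: -0.08, 18: -0.10, 24: -0.12}
ratio_intercept_sd: 0.25
ratio_residual_sd: 0.35
event_model:
  weibull_shape: 1.4
  weibull_scale_months: 180.0
  log_hr_active: -0.5
  beta_egfr: -0.03
  egfr_ref: 58.0
  beta_log_upcr: 0.5
  upcr_ref: 1.5
  death_fraction: 0.3
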