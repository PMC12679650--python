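# Comparator-trial scenario: a 404-subject parallel-arm RCT whose baseline
# marginals equal the comparator trial's published aggregate column (both
# threshold proportions are 50%, i.e. the published thresholds sit at the
# medians).  Comparator visits are generated on the index month grid; the
# published week labels (36/48/106) map onto months 9/12/24 via the
# timepoint map and are never interpolated.
trial_id: comparator
n: 404
allocation: 0.5
seed: 1
visit_months: [3, 6, 9, 12, 18, 24]
censor_month: 24
marginals:
  age: {dist: truncnorm, mean: 46.00, sd: 11.0, low: 18.0}
  male: {dist: bernoulli, p: 0.698}
  white: {dist: bernoulli, p: 0.6733}
  egfr: {dist: truncnorm, mean: 56.95, sd: 22.0, low: 10.0}
  upcr: {dist: lognormal, mean: 1.44, sigma: 0.60}
  uacr: {dist: lognormal, threshold: 1.1, exceed_prob: 0.50, sigma: 0.70}
  uprot24h: {dist: lognormal, threshold: 1.8, exceed_prob: 0.50, sigma: 0.60}
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
# continuous active treatment: steady moderate eGFR preservation
egfr_effects:
  active: {3: -0.3, 6: -0.6, 9: -1.0, 12: -1.4, 18: -2.0, 24: -2.8}
  control: {3: -1.0, 6: -2.0, 9: -3.0, 12: -4.0, 18: -5.2, 24: -6.5}
egfr_intercept_sd: 4.0
egfr_residual:
  sd: [5.0, 5.5, 6.0, 6.0, 6.5, 7.0]
  corr: 0.55
ratio_effects:
  upcr:
    active: {3: -0.30, 6: -0.40, 9: -0.50, 12: -0.55, 18: -0.55, 24: -0.55}
    control: {3: -0.05, 6: -0.08, 9: -0.10, 12: -0.10, 18: -0.12, 24: -0.12}
  uacr:
    active: {3: -0.35, 6: -0.48, 9: -0.58, 12: -0.62, 18: -0.62, 24: -0.62}
    control: {3: -0.05, 6: -0.08, 9: -0.10, 12: -0.12, 18: -0.12, 24: -0.14}
ratio_intercept_sd: 0.25
ratio_residual_sd: 0.35
event_model:
  weibull_shape: 1.4
  weibull_scale_months: 180.0
  log_hr_active: -0.35
  beta_egfr: -0.03
  egfr_ref: 58.0
  beta_log_upcr: 0.5
  upcr_ref: 1.5
  death_fraction: 0.3
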