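# Comparator-population aggregate matching targets (the published baseline
# column of the comparator trial), in the format read by
# maictools.trial_data.read_targets.  Proportions are on the percentage
# scale as printed.  The UACR threshold is 1.1 g/g for anchored (overall vs
# overall) and control-vs-control matching; active-vs-active unanchored
# matching uses 1.0 g/g instead (see the unanchored variant file).
targets:
  - {covariate: age, kind: mean, value: 46.00, source: comparator baseline table}
  - {covariate: male, kind: proportion, value: 69.80, scale: percent, source: comparator baseline table}
  - {covariate: white, kind: proportion, value: 67.33, scale: percent, source: comparator baseline table}
  - {covariate: egfr, kind: mean, value: 56.95, source: comparator baseline table}
  - {covariate: upcr, kind: mean, value: 1.44, source: comparator baseline table}
  - {covariate: uacr, kind: threshold_proportion, threshold: 1.1, direction: greater, value: 50.00, scale: percent, source: comparator baseline table}
  - {covariate: uprot24h, kind: threshold_proportion, threshold: 1.8, direction: greater, value: 50.00, scale: percent, source: comparator baseline table}
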