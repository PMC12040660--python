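# Full-pipeline configuration for `sersdx run-all`.
# Omit `simulate` and provide `spectra:`/`meta:` CSV paths to analyse
# your own data instead.
simulate:
  n_target: 48
  n_control: 30
  replicates_per_subject: 3
  effect_ratio: 2.0
  seed: 0

preprocess:
  sg_window: 15
  sg_polyorder: 1
  sg_deriv: 0
  baseline_degree: 15

evaluate:
  iterations: 30
  kfold: 7
  seed: 1
  vip_threshold: 1.0
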