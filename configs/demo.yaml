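# Small, fast demo of the full pipeline (seconds on one CPU).
seed: 1
simulate:
  n_subjects: 120
  n_cpgs: 800
  n_lmrs: 25
  lmr_cpg_range: [6, 14]
  n_signal_features: 40
  effect_size: 0.012
  n_age_features: 40
  age_effect_size: 0.008
segmentation:
  n_shuffles: 3
clock:
  n_lambda: 40
enrichment:
  n_perm: 100
  min_sources: 2
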