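# Default pipeline configuration (all values shown are the built-in defaults).
out_dir: runs/default
seed: 0
simulate: true
simulate_waveforms: false   # true = synthesize full 120-s EEG and run preprocessing
algorithm: spectral         # or fcm
k: 4
m: 1.7
alpha: 0.05
outlier_sd: 2.5
holdout_frac: 0.8
holdout_folds: 20
cohort:
  n_subjects: 56
  n_sessions: 4
  proportions: [0.25, 0.25, 0.25, 0.25]
  effect_size: 4.5
  session_jitter_cv: 0.05
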