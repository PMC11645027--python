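# Full default configuration for `locomo run --config configs/default.yaml`.
# Every key mirrors a dataclass field; omitted keys keep these same defaults.

seed: 42
out_dir: locomo_run
write_recordings: true

cohort:
  group_counts: {NonLS: 47, Stage1: 29, Stage2: 49, Young: 49}
  n_cycles: 5
  sample_rate_hz: 100.0
  between_subject_cv: 0.08
  # Per-group kinematics: separable-class configuration values, not
  # population measurements.
  group_kinematics:
    Young:  {cycle_duration_s: 1.5, duration_cv: 0.08, peak_pitch_velocity: 100.0,
             peak_ap_accel: 2.5, peak_si_accel: 2.0, tremor_noise_sd: 0.05,
             inter_cycle_pause_s: 0.30}
    NonLS:  {cycle_duration_s: 1.8, duration_cv: 0.08, peak_pitch_velocity: 85.0,
             peak_ap_accel: 2.0, peak_si_accel: 1.6, tremor_noise_sd: 0.05,
             inter_cycle_pause_s: 0.40}
    Stage1: {cycle_duration_s: 2.4, duration_cv: 0.10, peak_pitch_velocity: 70.0,
             peak_ap_accel: 1.5, peak_si_accel: 1.2, tremor_noise_sd: 0.06,
             inter_cycle_pause_s: 0.50}
    Stage2: {cycle_duration_s: 3.0, duration_cv: 0.12, peak_pitch_velocity: 55.0,
             peak_ap_accel: 1.1, peak_si_accel: 0.9, tremor_noise_sd: 0.07,
             inter_cycle_pause_s: 0.60}
  glfs_ranges:
    Young: null           # young participants are not staged
    NonLS: [0, 6]
    Stage1: [7, 15]
    Stage2: [16, 40]

preprocess:
  target_rate_hz: 50.0
  filter_order: 3
  cutoff_hz: 5.0
  zero_phase: true

segmentation:
  min_prominence: 20.0    # deg/s
  min_separation_s: 0.5
  boundary_fraction: 0.1
  differentiate: false

pipeline:
  test_fraction: 0.2
  split_seed: 42
  smote_enabled: true
  smote_k: 5
  paper_order: false      # true reproduces the literal SMOTE-before-split recipe
  pca_variance: 0.95
  select_k: null          # set to e.g. 40 to use mutual-information selection
  metric_average: weighted

mlp:
  hidden_layers: [512, 256, 128, 64, 32]
  l2: 0.001
  learning_rate: 0.001
  epochs: 200
  batch_size: 64
  early_stopping: true
  patience: 20
  validation_fraction: 0.1

models: [SVM-rbf, KNN, RF, LR, MLP]
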