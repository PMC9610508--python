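# Full-scale torso configuration. Body, scan, dataset sizes, noise level,
# training schedule and dense head follow the published study; exciter and
# receiver dimensions are a documented surrogate geometry (the published
# hardware drawings are not reproduced here) and can be overridden.
profile: paper
body:
  extent_cm: [50.0, 28.0, 24.0]
  fine_cm: 1.0
  coarse_cm: 2.0
exciter:
  n_wires: 11
  pitch_cm: 5.5
  wire_length_cm: 100.0
  z_cm: -5.0
receivers:
  wide_lobe_cm: 11.0
  narrow_lobe_cm: 3.6666666667
  wide_z_offset_cm: 5.0
  narrow_z_offset_cm: 7.0
scan:
  positions: 256
  trim: 25
  step_cm: 1.0
physics:
  frequency_hz: 1.5e+6
  signal_gain: 1.0
  emf_rule: midpoint
dataset:
  cases_1obj: 3000
  cases_2obj: 15000
  snr_db: 60.0
  length_range_cm: [6, 10]
  margin_cm: 0.0
  fractions: [0.65, 0.25, 0.10]
  seed: 2022
architecture:
  stem_filters: 64
  block_plan:
    - [residual, 64]
    - [bottleneck, 128]
    - [residual, 128]
    - [bottleneck, 256]
    - [residual, 256]
  dense_units: 5172
  n_dense: 2
  init: normal
  init_std: 1.0
training:
  phase1_delta: 1.0
  phase1_batch: 64
  phase1_epochs: 50
  phase2_delta: 0.05
  phase2_batch: 32
  phase2_epochs: 50
  learning_rate: 1.0e-3
  plateau_patience: 7
  plateau_factor: 0.1
  lr_floor: 1.0e-5
  early_stop_patience: 15
evaluation:
  overlap_extent_cm: 13.0
  unseen_sigma: 0.8
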