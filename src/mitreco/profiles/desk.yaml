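# Proportionally reduced configuration that trains on one CPU in minutes:
# half-scale body (24 x 12 x 12 cm), a 4x-body scan range with ~8% edge
# trim, perturbation edge lengths scaled to 4-8 cm, a 2,600-sample corpus
# and a narrow block plan with variance-scaled initialisation.  Physics,
# noise level (60 dB), conductivity values, coarsening and the two-phase
# Huber schedule are identical to the full-scale `paper` profile.
profile: desk
body:
  extent_cm: [24.0, 12.0, 12.0]
  fine_cm: 1.0
  coarse_cm: 2.0
exciter:
  n_wires: 11
  pitch_cm: 3.0
  wire_length_cm: 40.0
  z_cm: -4.0
receivers:
  wide_lobe_cm: 6.0
  narrow_lobe_cm: 2.0
  wide_z_offset_cm: 4.0
  narrow_z_offset_cm: 6.0
scan:
  positions: 96
  trim: 8
  step_cm: 1.0
physics:
  frequency_hz: 1.5e+6
  signal_gain: 1.0
  emf_rule: midpoint
dataset:
  cases_1obj: 500
  cases_2obj: 750
  snr_db: 60.0
  length_range_cm: [4, 8]
  margin_cm: 0.0
  fractions: [0.65, 0.25, 0.10]
  seed: 2022
architecture:
  stem_filters: 16
  block_plan:
    - [residual, 16]
    - [bottleneck, 32]
    - [residual, 32]
    - [bottleneck, 64]
    - [residual, 64]
  dense_units: 768
  n_dense: 2
  init: scaled
  init_std: 1.0
training:
  phase1_delta: 1.0
  phase1_batch: 64
  phase1_epochs: 35
  phase2_delta: 0.05
  phase2_batch: 32
  phase2_epochs: 35
  learning_rate: 1.0e-3
  plateau_patience: 7
  plateau_factor: 0.1
  lr_floor: 1.0e-5
  early_stop_patience: 15
evaluation:
  overlap_extent_cm: 10.0
  unseen_sigma: 0.8
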