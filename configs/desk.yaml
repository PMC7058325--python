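# Desk-scale defaults: every tunable of the pipeline, explicit.
# Coordinates everywhere: origin top-left, x=column, y=row, 0-based.
simulator:
  image_size: 128
  tree_depth: 6
  n_roots: 4
  root_diameter: 5.0
  murray_exponent: 3.0
  angle_mean: 75.0
  angle_sd: 12.0
  asymmetry_mean: 0.8
  asymmetry_sd: 0.12
  class_effect: -0.25
  angle_effect: 0.0
  effect_mode: bifurcation
  length_diameter_ratio: 8.0
  length_jitter: 0.25
  background_level: 0.8
  background_texture_sd: 0.05
  illumination_gradient: 0.15
  vessel_contrast: 0.55
  dark_vessels: true
  two_eye_probability: 0.4
  seed: 0
preprocess:
  target_side: 128
  gamma: 0.8333333333333334
  gamma_norm: 1.0
  clahe_tiles: 8
  clahe_clip: 0.01
  border_threshold: 0.05
  op_order: clahe_then_gamma
segmenter:
  depth: 2
  base_filters: 8
  patch_side: 32
  patches_per_image: 24
  epochs: 12
  batch_size: 16
  learning_rate: 0.002
  binarize_threshold: 0.5
  seed: 0
classifier:
  conv_filters:
  - 8
  - 12
  - 16
  - 16
  - 16
  kernel_sizes:
  - 3
  - 3
  - 3
  - 3
  - 3
  strides:
  - 1
  - 1
  - 1
  - 1
  - 1
  pool_sizes:
  - 2
  - 2
  - 2
  - 2
  - 0
  dense_units:
  - 32
  - 2
  dropout_rates:
  - 0.1
  - 0.1
  input_side: 128
  train_resize_side: 144
  epochs: 12
  batch_size: 16
  learning_rate: 0.003
  brightness_jitter: 0.2
  seed: 0
n_per_class: 60
n_segmenter_pairs: 30
attribution_radius: null
folds: 5
group_by_subject: true
seed: 0
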