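# Default reader-study geometry: 201 p.a. radiographs at 512x512,
# 20/53/67/61 cases with 0/1/2/3 nodules, 370 lesions with diameters
# 32x8mm, 111x10mm, 120x15mm, 107x20mm, 30-pixel COM matching radius.
study:
  composition: {0: 20, 1: 53, 2: 67, 3: 61}
  size_counts: {8: 32, 10: 111, 15: 120, 20: 107}
  output_size: 512
  unique_healthy_per_volume: true
  extent_range_mm: [8, 20]
phantoms:
  n_volumes: 21
  shape: [128, 128, 128]
  spacing: [2.5, 2.5, 2.5]
  noise_sd_hu: 20
  jitter: 0.04
attenuation:
  mu_water: 0.2059
  mu_air: 0.0
  S: 1000
nodules:
  n_shapes: 19
  base_diameter_mm: 12
  irregularity: 0.3
  soft_tissue_hu: 50
preprocess:
  table_threshold_hu: -300
  lung_threshold_hu: -400
  min_component_cm3: 1.0
evaluate:
  match_radius_px: 30
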