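colocalization:
  chance_correct: false
  offset_px:
  - 0.0
  - 0.0
  radius_px: 2.0
control: null
detection:
  min_separation_px: 2
  projection_frames: 10
  threshold_factor: 5.0
label: bait-partner-1to1
n_control_fields: null
n_fields: 4
seed: 0
simulation:
  background_level: 50.0
  bleach_prob_per_frame: 0.012
  channel_offset_px:
  - 0.0
  - 0.0
  channels:
  - copy_number_dist:
      1: 1.0
    label: A
    maturation_prob: 0.75
    unit_intensity: 300.0
  - copy_number_dist:
      1: 1.0
    label: B
    maturation_prob: 0.75
    unit_intensity: 300.0
  co_complex_fraction: 1.0
  field_height_px: 471
  field_width_px: 472
  n_frames: 300
  nonspecific_density: 0.0
  partner_only_density: 0.032
  pixel_size_nm: 150.0
  psf_sigma_px: 1.0
  read_noise_sd: 2.0
  seed: 0
  shot_noise: true
  surface_density: 0.016
steps:
  max_steps: 5
  min_dwell_frames: 2
  min_step_size: 0.0
  penalty: 3.0
stoichiometry:
  dominant_threshold: 0.1
  maturation_prob: 0.75
  n_max: 4
  n_restarts: 10
trace:
  annulus_radii_px:
  - 5.0
  - 7.0
  aperture_radius_px: 3.0
  max_traces_per_field: null
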