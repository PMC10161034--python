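# Example study configuration (moderate size; runs in ~40 s).
# Any omitted key takes its packaged default.
master_seed: 1
output_dir: study_out
save_volumes: false

cohort:
  n_subjects: 20
  # SSDE targets (mGy); each subject is reconstructed at every dose and
  # thickness. At 1.25 mm these map to SSDE_5.25 0.36-0.52 mGy (the fine
  # bins); at 5.25 mm they provide the coarse fallback levels.
  dose_grid: [1.5, 1.7, 1.9, 2.2]
  thickness_grid: [1.25, 5.25]
  truncation_probability: 0.3
  interval_days: {kind: mixture, low: 1, high: 90, p_short: 0.4, short_high: 14}
  drift:
    sat_mean_pct_per_day: 0.25
    sat_sd_pct_per_day: 0.05
    vat_mean_pct_per_day: 0.0
    vat_sd_pct_per_day: 0.0
  geometry:
    n_slices: 3
    n_rows: 192
    n_cols: 192
    pixel_spacing: 2.5
    slice_thickness: 5.25
    slice_interval: 5.0
    fov_diameter: 480.0

segmentation:
  fat_window: [-190.0, -30.0]
  denoiser: bilateral
  denoise_strength: 1.5

stats:
  alpha: 0.05
  bin_edges: [0.35, 0.40, 0.45, 0.50, .inf]
  interval_cutoff_days: 15
  acceptable_accuracy_mode: derived   # or: fixed (uses 94.5 / 85.2)
  small_n_min: 6

dosimetry:
  k: 0.015
  scan_length_cm: 16.8
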