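# One-shot pipeline configuration: simulate -> classify -> zonate -> sample
# -> cloud -> report.  Replace the `simulate` block with an `inputs` block
# (dem / stand_raster / stand_attributes paths) to analyse real rasters.
simulate:
  n_rows: 500
  n_cols: 500
  cell_size: 25.0        # m
  base_elev: 150.0       # m
  peak_elev: 1530.0      # m
  roughness: 15.0        # m, std of smoothed terrain noise
  patch_scale: 4         # cells per stand-patch side
  nonforest_frac: 0.30
  seed: 20240513
  belts:
    deciduous_broadleaf: {center_elev: 700.0, core_halfwidth: 150.0, lower_decay: 60.0, upper_decay: 40.0, aspect_shift: 30.0}
    temperate_conifer:   {center_elev: 1100.0, core_halfwidth: 150.0, lower_decay: 60.0, upper_decay: 40.0, aspect_shift: 30.0}
    mixed:               {center_elev: 1375.0, core_halfwidth: 75.0, lower_decay: 60.0, upper_decay: 40.0, aspect_shift: 30.0}

binning:
  width: 50.0            # m elevation bins

zones:
  floor_pct: 10.0        # main-range floor; per-type overrides possible:
  # overrides:
  #   deciduous_broadleaf: {main_range: [250.0, 1050.0], threshold_pct: 26.32}

sampling:
  spacing: 200.0         # m point grid
  elev_class_edges: [550.0, 900.0, 1100.0, 1350.0]

cloud:
  min_points: 3
  droplets: 2000
  seed: 20240513

report:
  figures: true
  pairs:
    - [deciduous_broadleaf, mixed]
    - [temperate_conifer, mixed]
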