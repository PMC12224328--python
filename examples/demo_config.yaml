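# Demo pipeline: synthesize every input, then analyze each of them.
# Run with:  nanocascade run --config examples/demo_config.yaml
seed: 7
outdir: results/demo
log_level: INFO
stages:
  simulate:
    tracks:
      n_tracks: 60
      diffusion_coeff: 21.19   # μm²/s
      frame_rate: 25.0         # Hz
      duration: 10.0           # s
    profiles:
      true_shift: 214.4        # μm, toward the solute inlet
      grid_spacing: 5.0
    cell_tracks:
      n_cells: 30
      mean_speed: 10.0         # μm/h
      persistence_time: 2.0    # h
      sampling_interval: 0.5
      duration: 24.0
    gap:
      initial_gap: 500.0       # μm
      closure_rate: 25.0       # μm/h
      times: [0.0, 6.0, 12.0, 18.0, 24.0]
      edge_roughness: 5.0
      pixel_size: 5.0
    growth:
      n0: 100.0
      doubling_time: 16.8      # h
      times: [0.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0]
      noise: {kind: additive-gaussian, sd: 0.05, relative: true}
    kinetics:
      model:
        production: {v_max: 1.0, k_m: 2.9}
        decomposition: {v_max: 5.0, k_half: 155.1, hill_h: 1.0}
      catalyst_conc: 0.1       # mg/mL
      glucose0: 10.0           # mM
      h2o2_0: 0.0
      times: [3.0, 6.0, 9.0]   # min
  analyze-tracks:
    path: results/demo/tracks.csv
    fit_window: 1.0
    max_lag: 1.0
    d_control: 21.19
  analyze-profiles:
    condition: results/demo/profile_condition.csv
    control: results/demo/profile_control.csv
  analyze-motility:
    path: results/demo/cell_tracks.csv
  analyze-gap:
    masks:
      - results/demo/gap_t0h.tiff
      - results/demo/gap_t6h.tiff
      - results/demo/gap_t12h.tiff
      - results/demo/gap_t18h.tiff
      - results/demo/gap_t24h.tiff
    times: [0.0, 6.0, 12.0, 18.0, 24.0]
  analyze-growth:
    path: results/demo/growth.csv
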