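# Annotated pipeline configuration for `clgfnet run --config <file>`.
# Every key is optional; omitted keys take the full study-condition
# defaults (see clgfnet.pipeline.RunConfig). Unknown keys are rejected.

seed: 1                       # global seed, fanned out per subject/stage
outdir: results/run1          # overridable with --out

# stages run in order; re-running a subset reuses nothing from disk, so
# keep prerequisite stages (simulate -> spectral -> switching, etc.)
stages: [simulate, spectral, switching, plv, infer, motifs, report]
# add "sweep" to include the CLGF local-coupling sweep of the circuit model

cohort:                       # synthetic two-group cohort (CohortSpec keys)
  n_subjects_per_group: [6, 6]   # control-like, patient-like
  n_channels: 20                 # 102 at full scale
  duration: 8.0                  # seconds (80 at full scale)
  fs: 1000.0                     # Hz
  noise_sd: 0.5                  # measurement noise / signal sd
  input_noise_sd: 0.3            # broadband drive noise in the dynamics
  coupling_strength: 2.0         # per-edge weight scale (/ sqrt degree)
  archetypes:                    # expected positive-FB abundances
    control: {local_mean: 4, global_mean: 3, clgf_mean: 2, count_sd: 1.0,
              n_negative: 1}
    patient: {local_mean: 2, global_mean: 2, clgf_mean: 0.5, count_sd: 0.8,
              n_negative: 1}
  score_r: -0.5                  # generating corr(negative score, CLGF count)

wavelet_width: 7.0            # Morlet cycles
plv_window_ms: 1000.0
plv_slide_ms: 200.0
topography_thresholds: [0.01, 0.001]   # raw per-edge p thresholds

ir_max_lag_ms: 35.0           # two-sided IR lag horizon (50 at full scale)
ir_surrogates: 100            # circular time-shift surrogates per pair
n_windows: 4                  # all-window consistency rule

sweep_grid: [0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0]
sweep_global_strength: 2.6    # calibrated 2-node beta-dominant regime
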