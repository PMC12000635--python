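# Default study configuration.
# Sequence timings are the printed acquisition parameters; the phantom tissue
# table carries 3T literature T1/PD values with apparent (FSE-readout) T2s and
# is explicitly configurable, not ground truth for any real scanner.
seed: 0
sequence:
  mprage:
    ti: 880.0      # ms
    tr_eff: 2300.0 # ms, effective recovery period standing in for the shot TR
    te: 2.2        # ms
  flair:
    ti: 1800.0
    tr: 5000.0
    te: 374.0
  ir:
    inversion_times: [50.0, 100.0, 200.0, 500.0, 1000.0, 2200.0, 3000.0]
    tr: 7000.0
    te: 10.0
grid:
  t1_min: 400.0
  t1_max: 3980.0
  step: 10.0
thresholds:
  wm_probability: 0.95   # pure-WM cut for the normalization reference
  tissue_probability: 0.95
  lesion_z: 3.0          # z-score above the WM FLAIR distribution
  min_lesion_component: 3
knn:
  k: 1
  standardize: false
evaluate:
  ssim_data_range: 4000.0  # ms, held fixed for cross-run comparability
  exclude_csf_from_pooled: true
phantom:
  shape: [96, 96, 96]
  voxel_size: [2.0, 2.0, 2.0]
  noise_sigma: 0.02      # Rician sigma relative to the WM signal (SNR 50)
  bias_amplitude: 0.0
  lesions:
    count: 5
    radius_range: [2.0, 4.0]
    t1_range: [1100.0, 1600.0]
    pd: 0.72
  tissue_table:          # name: [t1_ms, t2_apparent_ms, pd]
    wm:  [850.0, 300.0, 0.70]
    gm:  [1330.0, 380.0, 0.85]
    csf: [4200.0, 1800.0, 1.00]
    cau: [1250.0, 380.0, 0.85]
    gp:  [980.0, 300.0, 0.75]
    tha: [1150.0, 340.0, 0.80]
    put: [1120.0, 350.0, 0.80]
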