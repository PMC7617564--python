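# Synthetic two-condition study on a desk-scale grid.
# Run: vsasl simulate --config examples/phantom.yaml --out study/
seed: 7
physio:
  alpha: 0.56
  alpha_bgs: 0.86
  t1_blood: 1.6
  t1_tissue: 1.3
  lambda_bt: 0.9
timing:
  lct_values: [0.55, 0.66, 0.8, 0.96, 1.15, 1.39, 1.67, 2.0]
  crusher_to_readout: 0.050
  slice_delay: 0.0425
  n_slices: 4
mask:
  gm_pve_threshold: 0.50
  m0_fraction_threshold: 0.50
  region_pve_threshold: 0.25
phantom:
  grid: [16, 16, 4]
  n_subjects: 4
  noise_sd: 0.001
  n_pairs_per_lct: 4
  regions:
    - name: grey_matter
      cbf: {mean: 57, sd: 8}           # ml/100 g/min
      bolus_duration: {mean: 2.20, sd: 0.35}
      macro_bv: {mean: 0.0010, sd: 0.0007}
      macro_bolus_duration: {mean: 1.22, sd: 0.17}
  conditions:
    - name: normocapnia
    - name: hypercapnia
      cbf_scale: 1.45
      bolus_scale: 0.867
      macro_bv_scale: 1.5
      petco2_delta: {mean: 8.3, sd: 2.4}
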