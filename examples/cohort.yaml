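# Example cohort: study-sized groups with lesioned LGE-positive subjects.
seed: 42
output_dir: runs/demo
register: true
cohort:
  n_hcm: 16
  n_control: 14
  n_lge_positive: 9
  ecv_remote: {mean: 0.26, sd: 0.02}
  ecv_border: {mean: 0.35, sd: 0.03}
  ecv_core: {mean: 0.45, sd: 0.03}
  hct_hcm: {mean: 0.45, sd: 0.04, lo: 0.2, hi: 0.6}
  hct_control: {mean: 0.42, sd: 0.02, lo: 0.2, hi: 0.6}
  snr: 50
scheme:
  rr_interval: 1000
  base_tis: [100, 180, 260]
stages:
  report: true
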