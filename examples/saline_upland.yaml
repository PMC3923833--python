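name: saline-upland-example
biotic:
  z_min: -0.3
  z_peak: 0.45
  z_max: 1.2
  b_max: 1200.0
  rsr: 1.2
  turnover: 0.5
  k_decay: 0.4
  f_ref: 0.12
  d95: 25.0
physical:
  ssc: 200.0
  w_s: 25.0
  q_trap: 0.2
  n_tides: 704.0
  k_org: 0.085
  k_min: 1.99
datums:
  msl_cm: 95.0
  mhhw_cm: 185.0
thresholds:
  unveg_low: -0.3
  low_mid: 0.7
  mid_upland: 1.049
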