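name: brackish-island-example
biotic:
  z_min: -0.3
  z_peak: 0.5
  z_max: 1.3
  b_max: 2400.0
  rsr: 1.5
  turnover: 0.5
  k_decay: 0.3
  f_ref: 0.15
  d95: 30.0
physical:
  ssc: 100.0
  w_s: 25.0
  q_trap: 0.2
  n_tides: 704.0
  k_org: 0.085
  k_min: 1.99
datums:
  msl_cm: 100.0
  mhhw_cm: 180.0
thresholds:
  unveg_low: -0.3
  low_mid: 0.7
  mid_upland: 1.049
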