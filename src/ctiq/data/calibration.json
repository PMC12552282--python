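{
  "base_seed": 0,
  "k_lowest": 5,
  "lp_sigma": 2.0,
  "order_statistic_factor": {
    "0.0": 0.8138130452501523,
    "1.5": 0.5080512073600385
  },
  "region_diameter_px": 12,
  "window_radius": 3
}
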