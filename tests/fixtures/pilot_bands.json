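{
  "_comment": "Tolerance bands registered from a pre-build pilot run (5 replicate seeds 21-25 for fd recovery; seeds 31-33 for the scan fixture; none reused by the tests). Band rule: pilot mean +/- max(4*sd, 0.05).",
  "fd_recovery": {
    "0.1": {"pilot_mean": 0.116, "lo": 0.064, "hi": 0.168},
    "0.3": {"pilot_mean": 0.167, "lo": 0.087, "hi": 0.247},
    "0.5": {"pilot_mean": 0.246, "lo": 0.146, "hi": 0.346}
  },
  "type1_recall_min": 0.75,
  "strong_region_recall_min": 0.25,
  "decile_rho_max": -0.3
}
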