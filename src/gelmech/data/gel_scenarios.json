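{
  "nonaligned_0.03": {
    "group": "nonaligned",
    "gp_percent": 0.03,
    "max_load_g": 70.0,
    "params": {"C10_kPa": 11.0, "k1_kPa": 21000.0, "k2": 600.0, "gamma_deg": 45.0, "kappa": 0.333}
  },
  "nonaligned_0.1": {
    "group": "nonaligned",
    "gp_percent": 0.1,
    "max_load_g": 100.0,
    "params": {"C10_kPa": 16.5, "k1_kPa": 29750.0, "k2": 850.0, "gamma_deg": 45.0, "kappa": 0.333}
  },
  "nonaligned_0.25": {
    "group": "nonaligned",
    "gp_percent": 0.25,
    "max_load_g": 100.0,
    "params": {"C10_kPa": 17.0, "k1_kPa": 40250.0, "k2": 1150.0, "gamma_deg": 45.0, "kappa": 0.333}
  },
  "aligned_0.03": {
    "group": "aligned",
    "gp_percent": 0.03,
    "max_load_g": 70.0,
    "params": {"C10_kPa": 11.0, "k1_kPa": 5950.0, "k2": 170.0, "gamma_deg": 20.0, "kappa": 0.321}
  },
  "aligned_0.1": {
    "group": "aligned",
    "gp_percent": 0.1,
    "max_load_g": 100.0,
    "params": {"C10_kPa": 16.5, "k1_kPa": 10500.0, "k2": 300.0, "gamma_deg": 29.0, "kappa": 0.323}
  },
  "aligned_0.25": {
    "group": "aligned",
    "gp_percent": 0.25,
    "max_load_g": 100.0,
    "params": {"C10_kPa": 17.0, "k1_kPa": 11200.0, "k2": 320.0, "gamma_deg": 22.5, "kappa": 0.322}
  }
}
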