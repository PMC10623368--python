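{
  "_comment": "Default material registry. Optical absorption/scattering given in mm^-1 (converted to m^-1 on load). BegoStone optical scattering and quartz/BegoStone mechanical constants are literature/placeholder substitutes for unavailable supplementary values; override with a user file if measured properties are available.",
  "optical": {
    "water": {"mu_a_mm": 2.42, "mu_s_mm": 0.0, "g": 0.0, "n": 1.33},
    "vapor": {"mu_a_mm": 0.001, "mu_s_mm": 0.0, "g": 0.0, "n": 1.0},
    "begostone": {"mu_a_mm": 30.0, "mu_s_mm": 10.0, "g": 0.9, "n": 1.55},
    "quartz": {"mu_a_mm": 0.01, "mu_s_mm": 0.0, "g": 0.0, "n": 1.52}
  },
  "thermal": {
    "water": {"rho": 998.2, "cp": 4182.0, "k_cond": 0.598, "melt_T": 373.15, "latent_heat_vap": 2257000.0},
    "begostone": {"rho": 1995.0, "cp": 1100.0, "k_cond": 1.3, "melt_T": 423.15, "latent_heat_vap": 0.0}
  },
  "elastic": {
    "quartz": {"rho": 2200.0, "c_L": 5970.0, "c_T": 3760.0},
    "begostone": {"rho": 1995.0, "c_L": 4159.0, "c_T": 2319.0},
    "psm4": {"rho": 1180.0, "c_L": 2320.0, "c_T": 1100.0}
  },
  "fluid": {
    "water": {"rho": 998.2, "c": 1480.0, "p_stat": 101325.0, "p_v": 2339.0, "T0": 293.15}
  }
}
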