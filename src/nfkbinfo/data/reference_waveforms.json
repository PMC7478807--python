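{
  "TNF":     {"B": 0.05, "A": 1.0, "t_lag": 0.0,  "t_r": 8.0,  "t_0": 30.0,  "t_f": 120.0, "w": 0.6,  "T_osc": 95.0},
  "LPS":     {"B": 0.05, "A": 1.0, "t_lag": 0.0,  "t_r": 15.0, "t_0": 240.0, "t_f": 240.0, "w": 0.25, "T_osc": 120.0},
  "PolyIC":  {"B": 0.05, "A": 1.0, "t_lag": 60.0, "t_r": 45.0, "t_0": 240.0, "t_f": 240.0, "w": 0.0,  "T_osc": 100.0},
  "CpG":     {"B": 0.05, "A": 1.0, "t_lag": 0.0,  "t_r": 20.0, "t_0": 300.0, "t_f": 240.0, "w": 0.0,  "T_osc": 100.0},
  "Pam3CSK": {"B": 0.05, "A": 1.0, "t_lag": 0.0,  "t_r": 8.0,  "t_0": 20.0,  "t_f": 60.0,  "w": 0.0,  "T_osc": 100.0}
}
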