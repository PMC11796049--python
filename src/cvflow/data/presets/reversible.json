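{
  "E_start": 0.0,
  "E_vertex1": 0.5,
  "E_vertex2": 0.0,
  "scan_rate": 0.1,
  "n_cycles": 3,
  "E0": 0.25,
  "n_electrons": 1,
  "D": 1e-05,
  "C_bulk": 1e-06,
  "A": 0.0707,
  "C_dl": 0.0,
  "T": 298.15,
  "dt": 0.01,
  "noise_sigma_I": 0.0,
  "seed": 0,
  "oxidized_fraction": 0.5,
  "t_hold": 5.0
}
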