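{
  "profile_id": "gamry-cv",
  "identifiers": [
    {"scope": "filename", "pattern": "(?i)\\.dta$", "required": true},
    {"scope": "table-name", "pattern": "^CURVE", "required": true},
    {"scope": "header", "pattern": "^EXPERIMENTTYPE=CV$", "required": false}
  ],
  "data_map": {
    "table": 0,
    "x_column": "Vf",
    "y_column": "Im",
    "t_column": "T"
  },
  "metadata_map": [
    {"source": "TITLE", "target": "sample_id", "transform": {"type": "none"}},
    {"source": "SCANRATE", "target": "scan_rate", "transform": {"type": "scale", "factor": 0.001}},
    {"source": "VENDOR", "target": "instrument_vendor", "transform": {"type": "none"}},
    {"source": "computed:n_cycles", "target": "n_cycles", "transform": {"type": "none"}},
    {"source": "computed:potential_window", "target": "potential_window", "transform": {"type": "none"}}
  ],
  "output_policy": "one-file-per-cycle"
}
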