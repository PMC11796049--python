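{
  "profile_id": "palmsens-cv",
  "identifiers": [
    {"scope": "filename", "pattern": "(?i)\\.(csv|txt)$", "required": true},
    {"scope": "header", "pattern": "^Device=PalmSens", "required": true},
    {"scope": "header", "pattern": "^Method=Cyclic Voltammetry$", "required": false}
  ],
  "data_map": {
    "table": 0,
    "x_column": "E",
    "y_column": "i",
    "t_column": "t"
  },
  "metadata_map": [
    {"source": "Title", "target": "sample_id", "transform": {"type": "none"}},
    {"source": "Scan rate", "target": "scan_rate", "transform": {"type": "scale", "factor": 1.0}},
    {"source": "Device", "target": "instrument_vendor", "transform": {"type": "none"}},
    {"source": "computed:n_cycles", "target": "n_cycles", "transform": {"type": "none"}}
  ],
  "output_policy": "one-file-per-cycle"
}
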