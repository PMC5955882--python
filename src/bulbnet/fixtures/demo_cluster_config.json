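{
  "name": "cluster_gating",
  "out_dir": null,
  "params": {
    "amp": 0.45,
    "bin_ms": 10.0,
    "configs": [
      "no_columns",
      "columns",
      "columns_dsacs"
    ],
    "depth": 0.4,
    "duration": 2400.0,
    "inh_gain": 4.0,
    "learn_sniffs": 10,
    "n_dsac": 2,
    "n_gc": 240,
    "noise_rate": 40.0,
    "noise_w": 0.0004,
    "population": "mTC",
    "reach": 100.0,
    "settle": 300.0
  },
  "seed": 1
}
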