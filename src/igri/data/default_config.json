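{
  "normalization": {
    "bounds": {
      "PSD": [0.95, 16.9],
      "MD": [-24.1, 6.39],
      "RNFL_S": [6.0, 172.0],
      "RNFL_I": [0.0, 195.0],
      "RNFL_T": [20.0, 110.0],
      "IOP": [5.0, 29.0]
    },
    "reversed_features": ["MD", "RNFL_I", "RNFL_S", "RNFL_T"]
  },
  "index": {
    "weights": {
      "PSD": 0.27,
      "MD": 0.14,
      "RNFL_S": 0.11,
      "RNFL_I": 0.31,
      "RNFL_T": 0.1,
      "IOP": 0.07
    },
    "base_ratio": 0.8,
    "nni_ratio": 0.2,
    "threshold": 0.36,
    "staging_bins": {
      "advanced_below": -12.0,
      "intermediate_upper": -5.0
    },
    "k": 5,
    "border_margin": 0.05
  }
}
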