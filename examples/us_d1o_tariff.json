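{
  "coefficients": {
    "A2": -0.156,
    "A3": -0.45,
    "D1": 0.14,
    "I22": -0.011,
    "I3": 0.122,
    "I32": 0.015,
    "M2": -0.146,
    "M3": -0.558,
    "P2": -0.173,
    "P3": -0.537,
    "S2": -0.175,
    "S3": -0.471,
    "U2": -0.14,
    "U3": -0.374
  },
  "spec": "D1O",
  "standard_errors": {
    "A2": 0.008,
    "A3": 0.015,
    "D1": 0.01,
    "I22": 0.002,
    "I3": 0.018,
    "I32": 0.003,
    "M2": 0.008,
    "M3": 0.016,
    "P2": 0.008,
    "P3": 0.02,
    "S2": 0.008,
    "S3": 0.016,
    "U2": 0.008,
    "U3": 0.013
  }
}
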