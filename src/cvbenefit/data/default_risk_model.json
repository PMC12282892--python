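{
  "M": {
    "coefficients": {
      "age": 0.075,
      "smoker": 0.55,
      "sbp": 0.016,
      "tc": 0.22,
      "diabetes": 0.65
    },
    "covariate_means": {
      "age": 57.0,
      "smoker": 0.5,
      "sbp": 130.0,
      "tc": 4.8,
      "diabetes": 0.0
    },
    "transforms": {},
    "baseline_survival_10y": 0.90,
    "recalibration_divisor": 1.59
  },
  "F": {
    "coefficients": {
      "age": 0.08,
      "smoker": 0.6,
      "sbp": 0.015,
      "tc": 0.2,
      "diabetes": 0.7
    },
    "covariate_means": {
      "age": 57.0,
      "smoker": 0.05,
      "sbp": 130.0,
      "tc": 4.8,
      "diabetes": 0.0
    },
    "transforms": {},
    "baseline_survival_10y": 0.94,
    "recalibration_divisor": 1.72
  }
}
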