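{
  "generator": {
    "n": 7287,
    "target_population": 324600000.0,
    "prop_female": 0.517,
    "age_mean": 57.0,
    "age_sd": 10.0,
    "sbp_mean": 130.0,
    "sbp_sd": 18.0,
    "sbp_age_slope": 0.5,
    "tc_mean": 4.8,
    "tc_sd": 0.9,
    "ldl_given_tc_ratio": 0.62,
    "ldl_noise_sd": 0.35,
    "hdl_mean": 1.3,
    "hdl_sd": 0.3,
    "smoking_prob_male": 0.5,
    "smoking_prob_female": 0.05,
    "cvd_history_prob": 0.05,
    "diabetes_prob": 0.08,
    "statin_use_prob": 0.02,
    "seed": 0
  },
  "risk_model": null,
  "treatment": {
    "ldl_reduction_prop": 0.4,
    "rr_mode": "constant",
    "rr_constant": 0.78,
    "rr_interaction": null
  },
  "strategies": [
    {
      "kind": "risk_threshold",
      "threshold": 0.1,
      "label": "high_risk"
    },
    {
      "kind": "calibrated_benefit",
      "match_risk_threshold": 0.1,
      "label": "high_benefit"
    },
    {
      "kind": "minimum_benefit",
      "from_risk_threshold": 0.1,
      "label": "minimum_benefit"
    }
  ],
  "bootstrap": {
    "reps": 200,
    "seed": 0
  },
  "output": "results/run"
}
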