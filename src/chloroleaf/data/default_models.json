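[
  {
    "target": "chlorophyll_a",
    "intercept": -30.623,
    "coefficients": {
      "b": 1.143,
      "b_raw": -0.225,
      "h": 0.008,
      "s": 85.096,
      "v": -170.899
    },
    "feature_order": ["b", "b_raw", "h", "s", "v"],
    "metadata": "Five-feature MLR calibration for chlorophyll-a (mg/g), pooled wheat + maize leaves; predictors are normalized blue index (b), raw blue channel (b_raw), hue (deg), saturation and value (unit interval)."
  },
  {
    "target": "chlorophyll_b",
    "intercept": -13.164,
    "coefficients": {
      "b": 0.467,
      "b_raw": -0.052,
      "h": 0.005,
      "s": 35.536,
      "v": -72.08
    },
    "feature_order": ["b", "b_raw", "h", "s", "v"],
    "metadata": "Five-feature MLR calibration for chlorophyll-b (mg/g), pooled wheat + maize leaves."
  },
  {
    "target": "total_chlorophyll",
    "intercept": -43.787,
    "coefficients": {
      "b": 1.609,
      "b_raw": -0.276,
      "h": 0.013,
      "s": 120.632,
      "v": -242.979
    },
    "feature_order": ["b", "b_raw", "h", "s", "v"],
    "metadata": "Five-feature MLR calibration for total chlorophyll (mg/g), pooled wheat + maize leaves."
  }
]
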