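{
  "R_best_I": {
    "criterion": "R",
    "weights": {
      "DurNormWPW": -0.057,
      "F0MinW": -0.446,
      "F0MeanW": -0.195,
      "MeanJitter": 0.118,
      "MeanShimmer": 0.144,
      "NumVoiced": 0.321,
      "CFx": 0.210
    },
    "r": 0.71,
    "rho": 0.57,
    "significance": "<0.001"
  },
  "R_best_I_noCFx": {
    "criterion": "R",
    "weights": {
      "DurNormWPW": -0.046,
      "F0MinW": -0.458,
      "F0MeanW": -0.226,
      "MeanJitter": 0.186,
      "MeanShimmer": 0.138,
      "NumVoiced": 0.347
    },
    "r": 0.66,
    "rho": 0.49,
    "significance": "<0.001"
  },
  "R_best_II": {
    "criterion": "R",
    "weights": {
      "F0MinW": -0.452,
      "F0MeanW": -0.191,
      "MeanJitter": 0.113,
      "MeanShimmer": 0.145,
      "NumVoiced": 0.334,
      "CFx": 0.206
    },
    "r": 0.71,
    "rho": 0.58,
    "significance": "<0.001"
  },
  "R_best_II_noCFx": {
    "criterion": "R",
    "weights": {
      "F0MinW": -0.389,
      "F0MeanW": -0.172,
      "MeanJitter": 0.249,
      "MeanShimmer": 0.114,
      "NumVoiced": 0.324
    },
    "r": 0.67,
    "rho": 0.49,
    "significance": "<0.001"
  },
  "B_best": {
    "criterion": "B",
    "weights": {
      "DurNormWPW": 0.377,
      "F0OnW": 0.173,
      "EnNormW": -0.247,
      "MeanJitter": 0.239,
      "MeanShimmer": -0.031,
      "StandDevShimmer": -0.163
    },
    "r": 0.36,
    "rho": 0.27,
    "significance": "0.003"
  },
  "H_best_I": {
    "criterion": "H",
    "weights": {
      "DurNormW": 0.513,
      "F0OffPosW": 0.322,
      "EnNormW": -0.315,
      "MeanJitter": 0.366,
      "NumVoiced": 0.094,
      "RelNumVoicedUnvoiced": -0.164,
      "CQx": 0.643
    },
    "r": 0.53,
    "rho": 0.54,
    "significance": "<0.001"
  },
  "H_best_II": {
    "criterion": "H",
    "weights": {
      "DurNormWPW": 0.499,
      "F0OffPosW": 0.120,
      "EnNormWPW": -0.151,
      "MeanJitter": 0.368,
      "NumVoiced": -0.133,
      "RelNumVoicedUnvoiced": 0.218,
      "CQx": 0.495
    },
    "r": 0.47,
    "rho": 0.46,
    "significance": "<0.001"
  },
  "H_best_III": {
    "criterion": "H",
    "weights": {
      "DurNormWPW": 0.378,
      "F0OffPosW": 0.185,
      "EnNormW": 0.155,
      "MeanJitter": 0.320,
      "NumVoiced": -0.117,
      "RelNumVoicedUnvoiced": 0.082,
      "CQx": -0.242
    },
    "r": 0.45,
    "rho": 0.45,
    "significance": "<0.001"
  },
  "H_best_IV": {
    "criterion": "H",
    "weights": {
      "DurNormW": 0.402,
      "F0OffPosW": 0.236,
      "EnNormWPW": 0.343,
      "MeanJitter": 0.208,
      "NumVoiced": 0.122,
      "RelNumVoicedUnvoiced": -0.144,
      "CQx": 0.506
    },
    "r": 0.49,
    "rho": 0.55,
    "significance": "<0.001"
  },
  "R_cfx_cqx": {
    "criterion": "R",
    "weights": {
      "CFx": 0.303,
      "CQx": 0.033
    },
    "r": 0.31,
    "rho": 0.43,
    "significance": "0.009"
  },
  "B_cfx_cqx": {
    "criterion": "B",
    "weights": {
      "CFx": 0.091,
      "CQx": 0.117
    },
    "r": -0.1,
    "rho": -0.05,
    "significance": "0.228"
  },
  "H_cfx_cqx": {
    "criterion": "H",
    "weights": {
      "CFx": 0.34,
      "CQx": 0.49
    },
    "r": 0.44,
    "rho": 0.48,
    "significance": "<0.001"
  }
}
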