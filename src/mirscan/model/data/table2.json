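{
  "name": "complete-database",
  "source": "built-in multiple-regression model fit on the complete 18719-record sensor-assay database",
  "intercept": -43.85,
  "terms": {
    "dG": -2.694,
    "dG2": -0.06917,
    "dG3": -0.0005959,
    "dG1": 0.3705,
    "A_1": 0.8201,
    "A_2": 0.8225,
    "A_3": 0.6747,
    "A_4": 0.4644,
    "A_5": 0.5027,
    "A_11": 0.3433,
    "A_12": 0.4986,
    "A_13": 0.9504,
    "A_19": -0.4455,
    "A_20": -1.067,
    "A_22": 0.3039,
    "G_6": -0.3063,
    "G_7": -0.3133,
    "G_9": -0.2439,
    "G_10": -0.6907,
    "G_14": -0.4776,
    "G_17": -0.2477,
    "G_18": -0.2378,
    "G_19": -0.132,
    "G_21": 0.3678,
    "C_4": -0.239,
    "C_5": -0.3201,
    "C_7": -0.4681,
    "C_8": -0.1913,
    "C_10": -0.6128,
    "C_11": -0.2256,
    "C_13": -0.2326,
    "U_1": 1.989,
    "U_2": 0.6581,
    "U_3": 0.5757,
    "U_6": 0.5343,
    "U_10": -0.3281,
    "U_12": 0.5828,
    "U_13": 0.7992,
    "U_14": 0.6866,
    "U_17": 0.3141,
    "U_22": 0.3012
  }
}
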