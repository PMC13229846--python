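{
  "description": "Published PLS coefficient vectors relating carrot flesh colour (L*, a*, b*, C*, h deg) to pigment content in mg/100 g fresh weight. Two printed versions of the TCC WF0 model exist ('eq9' and 'table3:tcc'); both are shipped verbatim and neither is arbitrated. Coefficients apply to centred predictors (no intercept is printed).",
  "predictor_order": ["L_star", "a_star", "b_star", "C_star", "h_deg"],
  "models": {
    "eq8":  {"pigment": "tac", "light_condition": "WF0",
             "coefficients": [0.524, -255.3, -239.0, 437.4, 25.2]},
    "eq9":  {"pigment": "tcc", "light_condition": "WF0",
             "coefficients": [-1.71, 2.56, -9.70, 7.90, 5.43]},
    "eq10": {"pigment": "tac", "light_condition": "PF0",
             "coefficients": [20.1, -458.5, -402.6, 794.5, 10.0]},
    "eq11": {"pigment": "tcc", "light_condition": "PF0",
             "coefficients": [-2.77, 2.65, -11.2, 9.31, 6.55]},
    "table3:tac": {"pigment": "tac", "light_condition": "WF0",
                   "coefficients": [0.524, -255.3, -239.0, 437.4, 25.2],
                   "r2": 0.824, "rmsep": 15.09, "rmsep_pct": 40.7,
                   "content_range": [4.03, 80.5]},
    "table3:tcc": {"pigment": "tcc", "light_condition": "WF0",
                   "coefficients": [1.211, 4.877, -13.41, 16.13, 6.480],
                   "r2": 0.784, "rmsep": 2.27, "rmsep_pct": 32.4,
                   "content_range": [0.28, 20.5]},
    "table3:lutein": {"pigment": "lutein", "light_condition": "WF0",
                      "coefficients": [-0.01415, -0.06352, -0.04511, -0.07839, -0.003790],
                      "r2": 0.488, "rmsep": 0.13, "rmsep_pct": 34.1,
                      "content_range": [0.25, 0.92]},
    "table3:alpha_carotene": {"pigment": "alpha_carotene", "light_condition": "WF0",
                              "coefficients": [0.02682, -2.898, -12.42, 9.467, 4.052],
                              "r2": 0.435, "rmsep": 1.63, "rmsep_pct": 52.4,
                              "content_range": [0.25, 8.88]},
    "table3:beta_carotene": {"pigment": "beta_carotene", "light_condition": "WF0",
                             "coefficients": [0.354, -5.917, -24.53, 19.89, 6.291],
                             "r2": 0.428, "rmsep": 2.39, "rmsep_pct": 60.1,
                             "content_range": [0.25, 13.46]}
  }
}
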