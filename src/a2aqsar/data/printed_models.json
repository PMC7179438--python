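{
  "activity_cutoff": 5.64936,
  "training_outliers": ["2", "3", "4", "5", "8"],
  "models": {
    "tetra": {
      "intercept": 4.022064,
      "coefficients": {"MV": 0.019606, "MP": -0.720766, "NA": 0.216313, "HG": -0.139588},
      "reported": {"n": 16, "r": 0.9457, "r2": 0.8944, "r2_adj": 0.8560, "see": 0.3228, "f": 23.2970}
    },
    "penta": {
      "intercept": 4.478449,
      "coefficients": {"MV": 0.023246, "MP": -0.829411, "NA": 0.242268, "PF": -0.081025, "HG": -0.072964},
      "reported": {"n": 16, "r": 0.9634, "r2": 0.9281, "r2_adj": 0.8922, "see": 0.279, "f": 25.850}
    },
    "hexa": {
      "intercept": 3.916999,
      "coefficients": {"MV": 0.025762, "MP": -0.869548, "NA": 0.221891, "PF": -0.081625, "HG": -0.069166, "AR": 0.120464},
      "reported": {"n": 16, "r": 0.9653, "r2": 0.9318, "r2_adj": 0.8863, "see": 0.2868, "f": 20.5008}
    }
  }
}
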