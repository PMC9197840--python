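{
  "description": "Published case/control counts per ordered predictor level for the rapid-metastasis cSCC study cohorts (cases = rapid metastasis, n<=22; controls = non-metastatic, n<=59; unknowns excluded per variable, hence varying denominators).",
  "tables": {
    "gender": {
      "levels": ["female", "male"],
      "cases": [5, 17],
      "controls": [22, 37]
    },
    "grade": {
      "levels": ["1", "2", "3"],
      "cases": [8, 10, 4],
      "controls": [32, 18, 6]
    },
    "diameter": {
      "levels": ["<10", "10-19.9", "20-29.9", ">=30"],
      "cases": [2, 3, 5, 12],
      "controls": [22, 24, 7, 6]
    },
    "diameter_ge20": {
      "levels": ["<20", ">=20"],
      "cases": [5, 17],
      "controls": [46, 13]
    },
    "clark": {
      "levels": ["2-4", "5"],
      "cases": [4, 15],
      "controls": [44, 12]
    },
    "invasion_beyond_fat": {
      "levels": ["no", "yes"],
      "cases": [8, 13],
      "controls": [49, 10]
    },
    "ajcc8": {
      "levels": ["T1", "T2", "T3", "T4a-T4b"],
      "cases": [2, 3, 15, 1],
      "controls": [44, 3, 9, 3]
    },
    "bwh": {
      "levels": ["T1", "T2a", "T2b", "T3"],
      "cases": [1, 6, 13, 1],
      "controls": [36, 11, 7, 3]
    },
    "pathologist_prediction": {
      "levels": ["non_met", "met"],
      "cases": [7, 10],
      "controls": [40, 10]
    },
    "ai_prediction": {
      "levels": ["non_met", "met"],
      "cases": [8, 14],
      "controls": [45, 14]
    },
    "pathologist_clark": {
      "levels": ["0", "1", "2"],
      "cases": [2, 7, 8],
      "controls": [32, 11, 5]
    },
    "ai_clark": {
      "levels": ["0", "1", "2"],
      "cases": [0, 11, 8],
      "controls": [33, 22, 1]
    },
    "conventional_rfm": {
      "levels": ["0", "1", "2"],
      "cases": [2, 8, 9],
      "controls": [43, 10, 3]
    },
    "pathologist_rfm": {
      "levels": ["0", "1", "2", "3"],
      "cases": [2, 3, 6, 5],
      "controls": [31, 10, 7, 0]
    },
    "ai_rfm": {
      "levels": ["0", "1", "2", "3"],
      "cases": [0, 5, 9, 5],
      "controls": [32, 20, 4, 0]
    },
    "perineural_invasion": {
      "levels": ["not_present", "present"],
      "cases": [22, 0],
      "controls": [58, 1]
    }
  },
  "ai_confusion": {
    "rapid_met": {"pred_met": 14, "pred_non_met": 8},
    "non_met": {"pred_met": 14, "pred_non_met": 45}
  }
}
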