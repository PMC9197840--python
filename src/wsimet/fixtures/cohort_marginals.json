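{
  "description": "Per-cohort marginal level counts of baseline primary-tumor characteristics for the non-metastatic (n=59) and rapid-metastasis (n=22) cohorts; used as sampling weights by the synthetic cohort generator. The slow-metastasis cohort has no published baseline table and reuses the non-metastatic marginals.",
  "cohorts": {
    "non_met": {
      "n": 59,
      "sex": {"male": 37, "female": 22},
      "grade": {"1": 32, "2": 18, "3": 6, "unknown": 3},
      "diameter_class": {"<10": 22, "10-19.9": 24, "20-29.9": 7, ">=30": 6},
      "clark": {"2-4": 44, "5": 12, "unknown": 3},
      "invasion_beyond_fat": {"no": 49, "yes": 10, "unknown": 0},
      "ajcc8": {"T1": 44, "T2": 3, "T3": 9, "T4a-T4b": 3, "unknown": 0},
      "bwh": {"T1": 36, "T2a": 11, "T2b": 7, "T3": 3, "unknown": 2},
      "pathologist_pred": {"non_met": 40, "met": 10, "cannot_assess": 9},
      "age": {"mean": 77, "sd": 9, "min": 55, "max": 93}
    },
    "rapid_met": {
      "n": 22,
      "sex": {"male": 17, "female": 5},
      "grade": {"1": 8, "2": 10, "3": 4, "unknown": 0},
      "diameter_class": {"<10": 2, "10-19.9": 3, "20-29.9": 5, ">=30": 12},
      "clark": {"2-4": 4, "5": 15, "unknown": 3},
      "invasion_beyond_fat": {"no": 8, "yes": 13, "unknown": 1},
      "ajcc8": {"T1": 2, "T2": 3, "T3": 15, "T4a-T4b": 1, "unknown": 1},
      "bwh": {"T1": 1, "T2a": 6, "T2b": 13, "T3": 1, "unknown": 1},
      "pathologist_pred": {"non_met": 7, "met": 10, "cannot_assess": 5},
      "age": {"mean": 73, "sd": 10, "min": 46, "max": 93}
    }
  }
}
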