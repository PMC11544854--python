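{
  "comment": "hand-counted expectations for cohort_fixture.csv",
  "n_records": 12,
  "n_patients": 11,
  "score_counts": {"0": 1, "1": 0, "2": 1, "3": 2, "4": 4, "5": 1, "6": 3},
  "outcome_counts": {
    "healed_spontaneously": 8,
    "grafted": 3,
    "deep_refused_graft": 1
  },
  "n_dual_graded": 11,
  "median_days_to_graft": 9,
  "confusion_at_threshold_4_grafted_or_refused": {"a": 4, "b": 0, "c": 0, "d": 8}
}
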