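{
  "comment": "Validation-cohort answer marginals for the 3-year scoring interview. Collapsed answer groups (always/dont_know; 4-6/7-12/>12; the three 'regularly' categories) are split into sub-shares that sum exactly to the printed group totals.",
  "scoring_items": {
    "wheeze_with_cold": {"always": 0.75, "dont_know": 0.08, "no": 0.09, "sometimes": 0.08},
    "wheeze_attacks_12m": {"0-3": 0.47, "4-6": 0.30, "7-12": 0.15, ">12": 0.08},
    "sleep_disturbed_wheeze": {"never": 0.67, "only_at_attacks": 0.26, "regularly": 0.07},
    "breathless_after_words": {"no": 0.84, "yes": 0.16},
    "exercise_wheeze": {"no": 0.81, "yes": 0.19},
    "eczema_12m": {"no": 0.63, "yes": 0.37},
    "mother_asthma_12m": {"no": 0.92, "yes": 0.08},
    "father_asthma_12m": {"no": 0.94, "yes": 0.06}
  },
  "male_fraction": 0.54
}
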