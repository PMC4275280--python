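{
  "dialect": "mas90_3y",
  "mappings": [
    {"item_id": 1, "source_variable": "sex",
     "translation": {"female": "female", "male": "male"},
     "comparability": "perfect"},
    {"item_id": 2, "source_variable": "age",
     "translation": {"2": "2", "3": "3"},
     "comparability": "perfect"},
    {"item_id": 3, "source_variable": "wheeze_with_cold",
     "translation": {"always": "no", "dont_know": "no", "no": "yes", "sometimes": "yes"},
     "comparability": "very_good"},
    {"item_id": 4, "source_variable": "wheeze_attacks_12m",
     "translation": {"0-3": "0-3", "4-6": ">3", "7-12": ">3", ">12": ">3"},
     "comparability": "very_good"},
    {"item_id": 5, "source_variable": "sleep_disturbed_wheeze",
     "translation": {"never": "never", "only_at_attacks": "a_little", "regularly": "a_lot"},
     "comparability": "moderate"},
    {"item_id": 6, "source_variable": "breathless_after_words",
     "translation": {"no": "never", "yes": "sometimes"},
     "comparability": "moderate"},
    {"item_id": 7, "source_variable": "exercise_wheeze",
     "translation": {"no": "no", "yes": "yes"},
     "comparability": "good"},
    {"item_id": 8, "source_variable": null,
     "translation": {},
     "comparability": "absent"},
    {"item_id": 9, "source_variable": "eczema_12m",
     "translation": {"no": "no", "yes": "yes"},
     "comparability": "very_good"},
    {"item_id": 10, "source_variable": "mother_asthma_12m,father_asthma_12m",
     "translation": {"mother_asthma_12m:yes": "mother", "mother_asthma_12m:no": "",
                     "father_asthma_12m:yes": "father", "father_asthma_12m:no": ""},
     "comparability": "moderate"}
  ]
}
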