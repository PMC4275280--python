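{
  "comment": "Default sensitivity-analysis grid: one scenario per row of the validation study's summary table (primary row, secondary inclusion, secondary scoring, secondary outcomes).",
  "scenarios": [
    {"name": "primary", "inclusion": "primary_wheeze_or_cough", "scoring": "primary_zero_fill", "outcome": "primary_wheeze_and_drugs_8y"},
    {"name": "incl_all_available", "inclusion": "all_available", "scoring": "primary_zero_fill", "outcome": "primary_wheeze_and_drugs_8y"},
    {"name": "incl_nonallergic_parents", "inclusion": "nonallergic_parents", "scoring": "primary_zero_fill", "outcome": "primary_wheeze_and_drugs_8y"},
    {"name": "incl_wheeze_only", "inclusion": "wheeze_only", "scoring": "primary_zero_fill", "outcome": "primary_wheeze_and_drugs_8y"},
    {"name": "incl_cough_only", "inclusion": "cough_only", "scoring": "primary_zero_fill", "outcome": "primary_wheeze_and_drugs_8y"},
    {"name": "scoring_complement_earlier", "inclusion": "primary_wheeze_or_cough", "scoring": "complement_earlier", "outcome": "primary_wheeze_and_drugs_8y"},
    {"name": "scoring_impute_random", "inclusion": "primary_wheeze_or_cough", "scoring": "impute_random", "outcome": "primary_wheeze_and_drugs_8y", "n_reps": 100},
    {"name": "scoring_shuffle_null", "inclusion": "primary_wheeze_or_cough", "scoring": "shuffle_null", "outcome": "primary_wheeze_and_drugs_8y", "n_reps": 100},
    {"name": "outcome_wheeze_8y", "inclusion": "primary_wheeze_or_cough", "scoring": "primary_zero_fill", "outcome": "wheeze_8y"},
    {"name": "outcome_drugs_8y", "inclusion": "primary_wheeze_or_cough", "scoring": "primary_zero_fill", "outcome": "drugs_8y"},
    {"name": "outcome_physician_dx_8y", "inclusion": "primary_wheeze_or_cough", "scoring": "primary_zero_fill", "outcome": "physician_dx_ever_8y"},
    {"name": "outcome_any_asthma_20y", "inclusion": "primary_wheeze_or_cough", "scoring": "primary_zero_fill", "outcome": "any_asthma_to_20y"},
    {"name": "outcome_allergic_asthma_20y", "inclusion": "primary_wheeze_or_cough", "scoring": "primary_zero_fill", "outcome": "allergic_asthma_to_20y"},
    {"name": "outcome_wheeze_meds_13y", "inclusion": "primary_wheeze_or_cough", "scoring": "primary_zero_fill", "outcome": "wheeze_or_meds_13y"},
    {"name": "outcome_wheeze_meds_20y", "inclusion": "primary_wheeze_or_cough", "scoring": "primary_zero_fill", "outcome": "wheeze_or_meds_20y"},
    {"name": "outcome_airway_responsiveness_20y", "inclusion": "primary_wheeze_or_cough", "scoring": "primary_zero_fill", "outcome": "airway_responsiveness_20y"}
  ]
}
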