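sex,age,wheeze_with_cold,wheeze_attacks_12m,sleep_disturbed_wheeze,breathless_after_words,exercise_wheeze,eczema_12m,mother_asthma_12m,father_asthma_12m,expected_score
male,3,always,0-3,never,no,no,no,no,no,2
female,3,no,4-6,regularly,yes,yes,yes,yes,yes,12
male,3,sometimes,>12,only_at_attacks,no,yes,no,yes,no,8
female,3,dont_know,0-3,never,no,no,yes,no,no,2
male,3,no,7-12,regularly,yes,no,yes,no,yes,11
male,2,always,0-3,never,no,no,no,no,no,2
female,3,no,0-3,only_at_attacks,no,yes,yes,yes,yes,7
male,3,sometimes,4-6,never,yes,yes,no,no,no,8
female,3,always,>12,regularly,no,no,yes,no,no,6
male,3,no,0-3,,no,no,no,no,no,3
female,3,dont_know,4-6,only_at_attacks,yes,no,no,yes,no,7
male,3,always,0-3,only_at_attacks,no,yes,yes,no,yes,6
female,3,sometimes,7-12,regularly,yes,yes,yes,yes,yes,12
male,3,no,>12,never,no,no,no,no,yes,6
female,2,always,0-3,never,no,no,no,no,no,1
male,3,sometimes,0-3,only_at_attacks,no,no,yes,no,no,5
female,3,no,4-6,never,yes,yes,no,yes,yes,9
male,3,dont_know,7-12,regularly,yes,yes,yes,yes,no,11
female,3,always,0-3,never,no,yes,no,no,no,2
male,3,no,>12,only_at_attacks,yes,no,yes,yes,yes,11
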