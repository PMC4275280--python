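{
  "items": [
    {"id": 1, "label": "Child's sex",
     "categories": [{"code": "female", "points": 0}, {"code": "male", "points": 1}]},
    {"id": 2, "label": "Child's age in years at scoring",
     "categories": [{"code": "1", "points": 0}, {"code": "2", "points": 1}, {"code": "3", "points": 1}]},
    {"id": 3, "label": "Wheezing or whistling in the chest without a cold or flu, last 12 months",
     "categories": [{"code": "no", "points": 0}, {"code": "yes", "points": 1}]},
    {"id": 4, "label": "Number of wheeze attacks, last 12 months",
     "categories": [{"code": "0-3", "points": 0}, {"code": ">3", "points": 2}]},
    {"id": 5, "label": "Wheeze interfering with daily activities, last 12 months",
     "categories": [{"code": "never", "points": 0}, {"code": "a_little", "points": 1}, {"code": "a_lot", "points": 2}]},
    {"id": 6, "label": "Wheezing attacks causing shortness of breath",
     "categories": [{"code": "never", "points": 0}, {"code": "sometimes", "points": 2}, {"code": "always", "points": 3}]},
    {"id": 7, "label": "Exercise, laughing, crying or excitement causing wheeze or cough, last 12 months",
     "categories": [{"code": "no", "points": 0}, {"code": "yes", "points": 1}]},
    {"id": 8, "label": "Contact with dust, grass or pets causing wheeze or cough, last 12 months",
     "categories": [{"code": "no", "points": 0}, {"code": "yes", "points": 1}]},
    {"id": 9, "label": "Eczema ever",
     "categories": [{"code": "no", "points": 0}, {"code": "yes", "points": 1}]},
    {"id": 10, "label": "Parents ever suffered from wheezing, asthma or bronchitis", "additive": true,
     "categories": [{"code": "none", "points": 0}, {"code": "mother", "points": 1}, {"code": "father", "points": 1}]}
  ],
  "cuts": {"low": 5, "high": 10}
}
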