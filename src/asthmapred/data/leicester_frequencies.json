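{
  "source": "Development-cohort answer frequencies of the 10 scoring questions (n=1226)",
  "frequencies": {
    "1": {"female": 0.45, "male": 0.55},
    "2": {"1": 0.28, "2": 0.57, "3": 0.15},
    "3": {"no": 0.82, "yes": 0.18},
    "4": {"0-3": 0.45, ">3": 0.55},
    "5": {"never": 0.64, "a_little": 0.26, "a_lot": 0.10},
    "6": {"never": 0.65, "sometimes": 0.29, "always": 0.06},
    "7": {"no": 0.61, "yes": 0.39},
    "8": {"no": 0.93, "yes": 0.07},
    "9": {"no": 0.56, "yes": 0.44},
    "10.mother": {"no": 0.78, "yes": 0.22},
    "10.father": {"no": 0.83, "yes": 0.17}
  }
}
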