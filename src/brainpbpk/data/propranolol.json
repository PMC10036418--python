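{
  "label": "propranolol",
  "LT0": 100,
  "AF": 800000,
  "GT0": 20000,
  "KA_in_vitro": 290000,
  "KG_in_vitro": 3300,
  "PT": 5000,
  "VP": 0.01,
  "VT": 0.7,
  "k1": 1140,
  "k2": 0.06,
  "k3": 66,
  "k4": 0.943,
  "k5": 0.006,
  "k6": 0.52,
  "k7": 1740,
  "k8": 0.006,
  "k9": 0,
  "k10": 60,
  "b": 0.3,
  "s": 4600,
  "k": 0.023,
  "d": 0.0027,
  "V": 5.0
}
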