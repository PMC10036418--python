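{
  "label": "imipramine",
  "LT0": 100,
  "AF": 800000,
  "GT0": 20000,
  "KA_in_vitro": 42000,
  "KG_in_vitro": 1200,
  "PT": 5000,
  "VP": 0.01,
  "VT": 0.7,
  "k1": 5400,
  "k2": 0.06,
  "k3": 150,
  "k4": 2.1,
  "k5": 0.006,
  "k6": 0.5,
  "k7": 6000,
  "k8": 0.006,
  "k9": 0,
  "k10": 60
}
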