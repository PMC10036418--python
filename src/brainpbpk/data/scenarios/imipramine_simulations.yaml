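# Imipramine steady-state simulation set.
# Each entry is the basal parameter set plus the listed overrides.
# Scenarios without enhanced dissociation pin the in-capillary
# off-rates at k1 = k2*KG_in_vitro and k7 = k8*KA_in_vitro.
base: imipramine
mode: steady
scenarios:
  - label: sim11_basal
    overrides: {}
  - label: sim12_no_enhanced_dissociation
    overrides: {k1: 72, k7: 252}
  - label: sim13_cancer_plasma_proteins
    overrides: {AF: 600000, GT0: 70000}
  - label: sim14_fast_agp_kinetics
    overrides: {k1: 54000, k2: 0.6}
  - label: sim15_slow_agp_kinetics
    overrides: {k1: 540, k2: 0.006}
  - label: sim16_dissociation_limited
    overrides: {k1: 72, k7: 252, k3: 150000, k4: 2100}
  - label: sim17_active_efflux
    overrides: {k4: 21}
  - label: sim18_brain_metabolism
    overrides: {k9: 6}
  - label: sim19_metabolism_plus_ischemia
    overrides: {k9: 6, k10: 6}
  - label: sim20_efflux_plus_metabolism
    overrides: {k4: 21, k9: 6}
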