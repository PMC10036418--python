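# Propranolol steady-state simulation set.
# Each entry is the basal parameter set plus the listed overrides.
# Concentrations in nM, rate constants in min^-1, association rates in
# nM^-1 min^-1.  The "cancer plasma protein" scenario uses the albumin
# and AGP levels of metastatic cancer (600 uM and 70 uM).
base: propranolol
mode: steady
scenarios:
  - label: sim1_basal
    overrides: {}
  - label: sim2_no_enhanced_dissociation      # k1 = k2 * KG_in_vitro
    overrides: {k1: 198}
  - label: sim3_cancer_plasma_proteins
    overrides: {AF: 600000, GT0: 70000}
  - label: sim4_fast_agp_kinetics             # k1, k2 x10, same KG_in_vivo
    overrides: {k1: 11400, k2: 0.6}
  - label: sim5_slow_agp_kinetics             # k1, k2 /10, same KG_in_vivo
    overrides: {k1: 114, k2: 0.006}
  # dissociation-limited case: in-vitro KG, permeability x1000; efflux
  # keeps the symmetric-transport relation k4 = k3*VP/VT
  - label: sim6_dissociation_limited
    overrides: {k1: 198, k3: 66600, k4: 951.4285714285714}
  - label: sim7_active_efflux                 # k4 x10 (AET at the BBB)
    overrides: {k4: 9.4}
  - label: sim8_brain_metabolism
    overrides: {k9: 6}
  - label: sim9_metabolism_plus_ischemia      # k10 /10
    overrides: {k9: 6, k10: 6}
  - label: sim10_efflux_plus_metabolism
    overrides: {k4: 9.4, k9: 6}
  # supplementary variants
  - label: supp_PT_1000
    overrides: {PT: 1000}
  - label: supp_PT_500
    overrides: {PT: 500}
  - label: supp_k5_x10
    overrides: {k5: 0.06}
  - label: supp_k5_div10
    overrides: {k5: 0.0006}
  - label: sim30_no_plasma_binding            # symmetric k4 = k3*VP/VT
    overrides: {AF: 0, GT0: 0, k4: 0.9428571428571428}
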