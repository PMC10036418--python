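"""Published steady-state simulation tables, cell by cell, as printed.

Column order: GL0, AL0, LF0 (arterial); GL, AL, LF (capillary);
LM, PL, PF (brain); K_p,brain.  Values are strings so the printed
precision (hence the comparison tolerance) is preserved.
"""

PROPRANOLOL_ROWS = {
    "sim1_basal":
        ["61.7", "28.2", "10.2", "23.6", "55.8", "20.6", "20.6",
         "959", "4,040", "9.8"],
    "sim2_no_enhanced_dissociation":
        ["61.7", "28.2", "10.2", "61.7", "28.2", "10.2", "10.2",
         "526", "4,473", "5.4"],
    "sim3_cancer_plasma_proteins":
        ["87.4", "8.5", "4.1", "55.7", "29.6", "14.7", "14.7",
         "724", "4,276", "7.4"],
    "sim4_fast_agp_kinetics":
        ["61.7", "28.2", "10.2", "22.2", "56.8", "21.0", "21.0",
         "973", "4,026", "9.9"],
    "sim5_slow_agp_kinetics":
        ["61.7", "28.2", "10.2", "33.6", "48.6", "17.9", "17.9",
         "854", "4,145", "8.7"],
    "sim6_dissociation_limited":
        ["61.7", "28.2", "10.2", "61.7", "28.2", "10.2", "10.2",
         "526", "4,473", "5.4"],
    "sim7_active_efflux":
        ["61.7", "28.2", "10.2", "23.6", "55.8", "20.6", "2.1",
         "116", "4,883", "1.2"],
    "sim8_brain_metabolism":
        ["61.7", "28.2", "10.2", "20.2", "46.5", "17.1", "2.3",
         "130", "4,869", "1.3"],
    "sim9_metabolism_plus_ischemia":
        ["61.7", "28.2", "10.2", "7.61", "19.23", "6.96", "0.95",
         "54", "4,946", "0.55"],
    "sim10_efflux_plus_metabolism":
        ["61.7", "28.2", "10.2", "21.9", "51.2", "18.8", "1.2",
         "66", "4,934", "0.67"],
}

IMIPRAMINE_ROWS = {
    "sim11_basal":
        ["45.3", "51.9", "2.73", "11.3", "39.5", "49.2", "50.2",
         "1,880", "3,120", "19.3"],
    "sim12_no_enhanced_dissociation":
        ["45.3", "51.9", "2.73", "45.3", "51.9", "2.73", "2.78",
         "162", "4,838", "1.6"],
    "sim13_cancer_plasma_proteins":
        ["79.2", "19.4", "1.36", "33.1", "25.1", "41.9", "42.7",
         "1,695", "3,305", "17.4"],
    "sim14_fast_agp_kinetics":
        ["45.3", "51.9", "2.73", "11.0", "39.6", "49.4", "50.3",
         "1,884", "3,116", "19.3"],
    "sim15_slow_agp_kinetics":
        ["45.3", "51.9", "2.73", "14.1", "38.3", "47.6", "48.6",
         "1,843", "3,157", "18.9"],
    "sim16_dissociation_limited":
        ["45.3", "51.9", "2.73", "45.3", "51.9", "2.73", "2.77",
         "161", "4,839", "1.6"],
    "sim17_active_efflux":
        ["45.3", "51.9", "2.73", "11.3", "39.5", "49.2", "5.02",
         "284", "4,716", "2.9"],
    "sim18_brain_metabolism":
        ["45.3", "51.9", "2.73", "6.13", "20.8", "25.6", "6.78",
         "376", "4,624", "3.8"],
    "sim19_metabolism_plus_ischemia":
        ["45.3", "51.9", "2.73", "1.13", "3.94", "4.86", "1.29",
         "76", "4,924", "0.77"],
    "sim20_efflux_plus_metabolism":
        ["45.3", "51.9", "2.73", "8.97", "31.1", "38.6", "3.06",
         "177", "4,823", "1.8"],
}

# The published table prints LM = 2.78 for the no-enhanced-dissociation
# scenario but 2.77 for its dissociation-limited twin, although the two
# are mathematically identical inputs (the permeability scaling cancels).
# The exact value is 2.7822; that one cell is compared at two last-digit
# units instead of one.
WIDENED_CELLS = {("sim16_dissociation_limited", "LM"): 2.0}
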