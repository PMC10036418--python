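# brainpbpk

A physiologically based pharmacokinetic (PBPK) simulator of brain
delivery of drugs that circulate bound to plasma proteins. It is aimed
at DMPK and neuropharmacology scientists who want to ask: *how much of
the free drug my in-vitro plasma assay reports is actually available to
the brain in vivo?*

## The model

The drug distributes over three spaces: the systemic arterial plasma,
the brain capillary plasma (volume `VP`), and the post-vascular brain
(volume `VT`). In plasma it binds albumin (total `AF`, dissociation
constant `KA`) and alpha-1-acid glycoprotein (AGP/"globulin", total
`GT0`, constant `KG`); in brain it binds tissue proteins (total `PT`,
constant `KP = k6/k5`). Exchange across the blood–brain barrier (BBB)
is first-order (`k3` influx, `k4` efflux), capillary plasma turns over
with the cerebral blood flow rate constant `k10`, and `k9` is brain
metabolism.

The key mechanistic ingredient is **plasma-protein-mediated uptake
(PMU)**: the dissociation constant of the drug–protein complex *inside
the brain capillary* (`k1/k2` for AGP, `k7/k8` for albumin) may exceed
the in-vitro value, so protein-bound drug dissociates at the capillary
surface and becomes available for transport. When the in-capillary and
in-vitro constants are equal, the capillary free drug `LF` equals the
in-vitro free drug `LF0` exactly — no PMU — and that remains true even
if BBB permeability is raised 1,000-fold (the "dissociation-limited"
hypothesis produces no uptake from the bound pool).

The package provides:

* the **closed-form steady state** of all 11 variables (arterial
  `GL0, AL0, LF0, GF0`; capillary `GL, AL, LF, GF`; brain `LM, PL,
  PF`) for a constant total plasma level `LT0`, with the derived
  ratios `K_p,brain = (PL+LM)/LT0` and `K_p,uu = LM/LF =
  (k3·VP)/(k4·VT)` when `k9 = 0`;
* **oral-dose time courses**: a one-compartment Bateman plasma input
  drives the seven capillary/brain ODEs (stiff BDF integration) with
  trapezoid AUC summaries;
* a **scenario engine and CLI** that applies named parameter overrides
  to the packaged basal parameter sets for propranolol (modest PMU,
  AGP pool only) and imipramine (strong PMU, both pools) and
  regenerates the full published simulation tables;
* an independent **stationary-point oracle** (root search on the ODE
  right-hand sides) cross-validating the closed form.

## Worked example

```bash
$ brainpbpk steady --drug propranolol
      label       GL0       AL0       LF0        GL        AL        LF        LM         PL          PF  Kp_brain
propranolol    61.649    28.148    10.204    23.630    55.797    20.572    20.569    959.059    4040.941     9.796
```

Reading the row: an in-vitro plasma assay would report 10.2 nM free
propranolol (`LF0`, fu = 0.10), but because the in-capillary AGP
dissociation constant (19 µM) exceeds the in-vitro one (3.3 µM), the
bioavailable capillary drug `LF` and the free brain drug `LM` are
20.6 nM — a 102 % enhancement. Brain tissue binding concentrates total
drug to `K_p,brain` ≈ 9.8 without touching `LM`.

Adding an active-efflux transporter (ten-fold selective increase of
`k4`) strips free drug from brain but not from the capillary:

```bash
$ brainpbpk steady --drug propranolol --set k4=9.4
      label  ...      LF       LM       PL        PF  Kp_brain
propranolol  ...  20.572    2.063  116.278  4883.722     1.183
```

The same engine runs batches and sweeps:

```bash
brainpbpk table --specs src/brainpbpk/data/scenarios/propranolol_simulations.yaml --out table.csv
brainpbpk sweep --drug propranolol --param PT --values 100:10000:log10 --out sweep.csv
brainpbpk oral  --drug propranolol --set AF=600000 --set GT0=70000 --out tc.csv --auc auc.csv
```

The oral run prints, among others, `AUC_LF/AUC_LF0 = 3.556` (the
bioavailable exposure exceeds the in-vitro free exposure by ~256 %) and
`AUC_(LM+PL)/AUC_LT0 = 7.218` (total brain to total plasma exposure).

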