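# Methods

## Model structure

The simulator is a partly flow, partly compartmental PBPK model with
three spaces: systemic arterial plasma, brain capillary plasma
(volume `VP`, basal 0.01 L/kg) and post-vascular brain (volume `VT`,
basal 0.7 L/kg). Eleven concentrations (all nM) describe the drug and
its carriers:

| space | variables |
|---|---|
| arterial | `GL0` (AGP-bound drug), `AL0` (albumin-bound), `LF0` (free, = in-vitro C_u,plasma), `GF0` (free AGP) |
| capillary | `GL`, `AL`, `LF` (free/bioavailable, = in-vivo C_u,plasma), `GF` |
| brain | `LM` (free, = in-vivo C_u,brain), `PL` (tissue-protein-bound), `PF` (free tissue protein) |

Free albumin is approximated by the total albumin `AF` throughout
(`AF` is three to four orders above the drug concentration), while AGP
occupancy is resolved exactly. Single-site mass action is assumed for
every binding reaction; drug–receptor binding is out of scope.

### Arterial equilibrium

The arterial compartment changes slowly relative to the capillary, so
its composition is the in-vitro equilibrium at the in-vitro
dissociation constants. The AGP-bound pool solves

    GL0 = 0.5·KG·(B − √(B² − 4·GT0·LT0/KG²)),
    B   = 1 + AF/KA + (GT0 + LT0)/KG,

implemented in the algebraically identical conjugate form
`2·GT0·LT0 / (KG·(B + √…))`, which is immune to floating-point
cancellation when the bound pool is small. Then `GF0 = GT0 − GL0`,
`LF0 = LT0/(1 + AF/KA + GF0/KG)` and `AL0 = (AF·LT0/KA)/(same)`. The
smaller quadratic root is the physical one; the larger always exceeds
`min(GT0, LT0)`. Degenerate inputs (`GT0 = 0` or `LT0 = 0`) bypass the
quadratic with `GL0 = 0`.

### Closed-form steady state

With `LT0` constant (IV infusion), the stationarity conditions of the
capillary/brain balance reduce to a quadratic in the free brain drug:

    LM = (VP/VT) · [√((a2 + a1·b1)² + 4·a2·b1·(b2 − a1)) − (a2 + a1·b1)]
                   / (2·a2·b1)

with aggregates

    a1 = k10·GF0 − k10·LF0 − k7·k10·AL0/(k7 + k10)
    a2 = k9 + [k10·(k4 + k9)/k3]·[1 + k8·AF/(k7 + k10)]
    b1 = k2·(k4 + k9)/(k3·(k1 + k10))
    b2 = k10·GF0 + k1·k10·GL0/(k1 + k10)

The positive ("+√") root is taken; the other root is negative for all
valid parameter sets tested, and nonnegativity is asserted. When
`k2 = 0` the quadratic degenerates to the linear `(b2 − a1)/a2`; when
`GT0 = 0` the positive root reduces analytically to `−a1/a2`, which
makes `GF = 0` exactly, so no special-casing is needed. The remaining
variables follow algebraically:

    LF = (k4 + k9)/k3 · (VT/VP) · LM        GF = (a1 + a2·LM·VT/VP)/k10
    AL = (k10·AL0 + k8·AF·LF)/(k7 + k10)    GL = (k10·GL0 + k2·LF·GF)/(k1 + k10)
    PF = PT/(1 + (k5/k6)·LM)                PL = PT − PF

Note the aggregates contain no `PT`, `k5` or `k6`: the free brain drug
and `K_p,uu = LM/LF` are structurally independent of brain tissue
binding, whereas `K_p,brain = (PL + LM)/LT0` is governed by it. With no
metabolism, `K_p,uu` equals the permeability ratio
`PS_influx/PS_efflux = (k3·VP)/(k4·VT)`; with `k9 > 0` the package
reports the realized `LM/LF` instead.

### Non-steady state

A single oral dose enters through the one-compartment Bateman input
`LT0(t) = b·s·k/(V·(k−d))·(e^(−d·t) − e^(−k·t))` (`b`
bioavailability, `s` dose in nmol/kg, `k` absorption and `d`
elimination rate constants, `V` systemic distribution volume). The
degenerate flip-flop case `k = d` is rejected. The arterial variables
are algebraic quasi-equilibrium functions of `LT0(t)`; seven ODEs
propagate the capillary and brain pools, with BBB exchange written
per-compartment volume (`k4·LM·VT/VP` into the capillary, `k3·LF·VP/VT`
into brain — implemented exactly as formulated, with no symmetrization
applied). Initial conditions: every drug species 0, `GF0 = GF = GT0`,
`PF = PT`. The pair `dPL/dt = −dPF/dt` conserves `PL + PF = PT`
analytically; the integration keeps it to ~1e-12 relative.

## Numerical choices

* **Stiff integration.** Rate constants span 0.0027–6,000 min⁻¹, so
  `scipy.integrate.solve_ivp` with the BDF method is used at
  `rtol = 1e-8`, `atol = 1e-10` nM. Explicit methods stall on this
  system.
* **Output grid and AUC.** Default 1-min steps over 1,440 min; AUCs by
  the composite trapezoid on that grid. Halving the step changes every
  AUC by well under 0.1 %.
* **Stationary oracle.** An independent check solves the ODE
  right-hand sides for zero (with `PF = PT − PL` substituted to remove
  the conserved direction) using `scipy.optimize.root` (Powell hybrid)
  started from the arterial composition; convergence is judged on the
  residual norm. Closed form and oracle agree to 1e-6 relative across
  wide log-uniform random parameter draws.
* **Arterial root.** Conjugate-form quadratic root (above) keeps the
  binding-equilibrium residual below 1e-8 relative even for trace
  bound pools.

## Parameters

Basal parameter sets for propranolol and imipramine ship as JSON
(`src/brainpbpk/data/`): `LT0 = 100` nM (pharmacologic plasma level),
`AF = 800 µM`, `GT0 = 20 µM` (healthy human plasma), `PT = 5,000` nM,
`k10 = 60` min⁻¹ (1-s capillary transit). Derivation rules:
`k1 = k2·KG_in_vivo`, `k7 = k8·KA_in_vivo`, `k3 = (PS/F)·k10`,
`k4 = k3·VP/VT` (symmetric passive transport). Two imipramine
constants are published only as bounds and are pinned to them
(`k6 = 0.5` min⁻¹, `k7 = 6,000` min⁻¹); they reproduce the reference
simulation table. The "metastatic cancer" plasma-protein scenario uses
`AF = 600 µM` and `GT0 = 70 µM`.

Scenario files are declarative (base drug + overrides) so the packaged
simulation sets double as documentation. One deliberate deviation: the
dissociation-limited propranolol scenario keeps the symmetric relation
`k4 = k3·VP/VT` (= 951.43 min⁻¹ at `k3 = 66,600`) rather than a
rounded efflux constant, because only the symmetric value preserves
the defining property of that scenario (`LF = LM = LF0`, identical to
the no-enhanced-dissociation case).

## What the packaged scenarios do and do not show

The packaged inputs are the published basal parameter sets, not
synthetic data; everything the tests assert is a property of the model
under those inputs. They demonstrate mechanistic consequences —
enhanced dissociation produces PMU, tissue binding shapes `K_p,brain`
but not free brain drug, active efflux and metabolism deplete `LM` —
not predictions validated against new experimental concentrations.
Species differences in plasma proteins, saturable transport,
multi-dose regimens, receptor binding and spatially distributed
(Krogh-cylinder) capillary geometry are all outside the model.

A further caveat: the oral-dose AUC *ratios* (LF vs LF0 enhancement,
brain-to-plasma exposure) are robust, scale-invariant outputs, but the
absolute AUC of the plasma input implied by the Bateman parameters is
about twice the absolute value quoted alongside the original time
courses, an inconsistency that cannot be resolved from the printed
inputs (the same parameters do reproduce the stated 100 nM crossing at
360–480 min). Absolute AUCs should therefore be interpreted relative
to the input function actually used.

## Limitations

* Arterial quasi-equilibrium means the model is not suited to
  second-scale transients in systemic binding.
* Free albumin ≈ total albumin fails if drug approaches albumin
  concentrations (≥ 100 µM total drug).
* `K_p,uu` reporting assumes passive BBB transport plus optional
  first-order efflux/metabolism; carrier saturation is not modeled.
* The oral module ships parameters for propranolol only; imipramine
  oral kinetics require a user-supplied `OralPKParameters` file.
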