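"""Closed-form steady state of the capillary/brain model.

At steady state under a constant total plasma drug level, the eleven
model variables satisfy a quadratic in the free brain drug LM whose
coefficients aggregate the flow, binding, transport and metabolism
rates.  An independent numerical stationary-point solver (root search
on the ODE right-hand sides) is provided as a cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .parameters import DrugParameterSet
from .plasma_binding import ArterialState, solve_arterial_equilibrium
from .nonsteady import capillary_brain_rhs

__all__ = [
    "ClosedFormIntermediates",
    "SteadyStateSolution",
    "solve_steady_state",
    "stationary_oracle",
    "kp_uu",
]


@dataclass(frozen=True)
class ClosedFormIntermediates:
    """Aggregate coefficients of the quadratic for free brain drug LM.

    a1/b2 collect the net arterial inflows of free/bound globulin drug
    (nM min^-1), a2 the first-order loss pathway (min^-1) and b1 the
    globulin re-association coupling (nM^-1).
    """

    B: float
    a1: float
    a2: float
    b1: float
    b2: float


@dataclass(frozen=True)
class SteadyStateSolution:
    """All eleven steady-state variables plus derived partition ratios."""

    arterial: ArterialState
    GL: float  #: capillary globulin-bound drug (nM)
    AL: float  #: capillary albumin-bound drug (nM)
    LF: float  #: capillary free (bioavailable) drug, C_u,plasma in vivo (nM)
    GF: float  #: capillary free globulin (nM)
    LM: float  #: free drug in brain, C_u,brain in vivo (nM)
    PL: float  #: tissue-protein-bound drug in brain (nM)
    PF: float  #: free tissue protein (nM)
    intermediates: ClosedFormIntermediates | None = None

    @property
    def Kp_brain(self) -> float:
        """Total brain to total plasma partition, (PL + LM)/LT0."""
        return (self.PL + self.LM) / self.arterial.LT0

    @property
    def kpuu(self) -> float:
        """Unbound partition coefficient K_p,uu = LM/LF."""
        return self.LM / self.LF

    @property
    def fu_in_vitro(self) -> float:
        """In-vitro fraction unbound, LF0/LT0."""
        return self.arterial.LF0 / self.arterial.LT0

    @property
    def fu_in_vivo(self) -> float:
        """In-vivo (bioavailable) fraction unbound in the capillary, LF/LT0."""
        return self.LF / self.arterial.LT0

    def as_row(self) -> dict[str, float]:
        """Flatten to the tabular report schema (arterial, capillary, brain)."""
        a = self.arterial
        return {
            "GL0": a.GL0, "AL0": a.AL0, "LF0": a.LF0,
            "GL": self.GL, "AL": self.AL, "LF": self.LF,
            "LM": self.LM, "PL": self.PL, "PF": self.PF,
            "Kp_brain": self.Kp_brain,
        }


def _intermediates(p: DrugParameterSet, art: ArterialState,
                   B: float) -> ClosedFormIntermediates:
    a1 = (p.k10 * art.GF0 - p.k10 * art.LF0
          - p.k7 * p.k10 * art.AL0 / (p.k7 + p.k10))
    a2 = p.k9 + (p.k10 * (p.k4 + p.k9) / p.k3) * (
        1.0 + p.k8 * p.AF / (p.k7 + p.k10))
    b1 = p.k2 * (p.k4 + p.k9) / (p.k3 * (p.k1 + p.k10))
    b2 = p.k10 * art.GF0 + p.k1 * p.k10 * art.GL0 / (p.k1 + p.k10)
    return ClosedFormIntermediates(B=B, a1=a1, a2=a2, b1=b1, b2=b2)


def solve_steady_state(params: DrugParameterSet,
                       total_drug: float | None = None) -> SteadyStateSolution:
    """Closed-form steady state for a constant total plasma drug level.

    The free brain drug solves

        LM = (VP/VT) * [sqrt((a2 + a1*b1)^2 + 4*a2*b1*(b2 - a1))
                        - (a2 + a1*b1)] / (2*a2*b1)

    (the positive root; the other is negative for valid parameters),
    after which the capillary variables follow algebraically:

        LF = (k4 + k9)/k3 * (VT/VP) * LM
        GF = [a1 + a2*LM*(VT/VP)] / k10
        AL = (k10*AL0 + k8*AF*LF) / (k7 + k10)
        GL = (k10*GL0 + k2*LF*GF) / (k1 + k10)
        PF = PT / (1 + (k5/k6)*LM),  PL = PT - PF

    Brain-tissue binding (PT, k5, k6) appears only in PL/PF: the free
    brain drug LM is structurally independent of tissue binding.
    """
    p = params
    art = solve_arterial_equilibrium(p, total_drug)
    alb = p.AF / p.KA_in_vitro if p.AF > 0 else 0.0
    tot = (p.GT0 + art.LT0) / p.KG_in_vitro if p.GT0 > 0 else 0.0
    inter = _intermediates(p, art, B=1.0 + alb + tot)
    a1, a2, b1, b2 = inter.a1, inter.a2, inter.b1, inter.b2
    if a2 <= 0:
        raise ValueError(f"invalid parameter set: a2 = {a2} <= 0 ({inter})")

    if b1 > 0:
        s = a2 + a1 * b1
        disc = s * s + 4.0 * a2 * b1 * (b2 - a1)
        if disc < 0:
            raise ValueError(f"negative discriminant in LM quadratic ({inter})")
        lm_unscaled = (math.sqrt(disc) - s) / (2.0 * a2 * b1)
    else:
        # k2 = 0 (no globulin re-association): quadratic degenerates to linear
        lm_unscaled = (b2 - a1) / a2

    LM = (p.VP / p.VT) * lm_unscaled
    if LM < 0:
        raise ValueError(f"negative LM root ({inter})")
    LF = ((p.k4 + p.k9) / p.k3) * (p.VT / p.VP) * LM
    GF = (a1 + a2 * lm_unscaled) / p.k10 if p.GT0 > 0 else 0.0
    AL = (p.k10 * art.AL0 + p.k8 * p.AF * LF) / (p.k7 + p.k10)
    GL = (p.k10 * art.GL0 + p.k2 * LF * GF) / (p.k1 + p.k10)
    if p.k6 > 0:
        PF = p.PT / (1.0 + (p.k5 / p.k6) * LM)
    else:
        PF = 0.0 if p.k5 * LM > 0 else p.PT
    PL = p.PT - PF
    return SteadyStateSolution(arterial=art, GL=GL, AL=AL, LF=LF, GF=GF,
                               LM=LM, PL=PL, PF=PF, intermediates=inter)


def stationary_oracle(params: DrugParameterSet,
                      total_drug: float | None = None) -> SteadyStateSolution:
    """Steady state by root search on the ODE right-hand sides.

    Independent of the closed form: holds LT0 constant, substitutes
    PF = PT - PL (the conserved tissue-protein pool), and solves the
    six remaining stationarity conditions with a Newton-type method
    started from the arterial composition.
    """
    p = params
    art = solve_arterial_equilibrium(p, total_drug)

    def residual(x):
        GL, AL, LF, GF, LM, PL = x
        y = np.array([GL, AL, LF, GF, LM, PL, p.PT - PL])
        r = capillary_brain_rhs(y, art, p)
        return np.concatenate([r[:5], [r[5]]])

    scale = max(art.LT0, 1.0)
    x0 = np.array([art.GL0, art.AL0, art.LF0, art.GF0,
                   art.LF0, min(0.5 * p.PT, scale)])
    sol = optimize.root(residual, x0, method="hybr", options={"xtol": 1e-12})
    # judge convergence on the residual itself: hybr can report lack of
    # progress after it has already landed on the root
    res_norm = float(np.linalg.norm(residual(sol.x)))
    if res_norm > 1e-6 * max(p.k10 * scale, 1.0):
        raise RuntimeError(
            f"stationary-point search did not converge: {sol.message} "
            f"(residual norm {res_norm:.3e})")
    GL, AL, LF, GF, LM, PL = sol.x
    return SteadyStateSolution(arterial=art, GL=GL, AL=AL, LF=LF, GF=GF,
                               LM=LM, PL=PL, PF=p.PT - PL)


def kp_uu(params: DrugParameterSet) -> float:
    """Unbound brain-to-plasma partition coefficient K_p,uu.

    With no brain metabolism (k9 = 0) this is the permeability ratio
    PS_influx/PS_efflux = (k3*VP)/(k4*VT); with metabolism it is the
    realized LM/LF of the full steady-state solution.
    """
    p = params
    if p.k4 <= 0 or p.VT <= 0:
        raise ValueError("k4 and VT must be > 0")
    if p.k9 == 0:
        return (p.k3 * p.VP) / (p.k4 * p.VT)
    return solve_steady_state(p).kpuu
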