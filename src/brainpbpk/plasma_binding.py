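"""Systemic (arterial) drug-albumin-AGP binding equilibrium.

The arterial compartment is assumed to equilibrate slowly relative to
the brain capillary, so its composition is the in-vitro mass-action
equilibrium of the drug with albumin and AGP at the in-vitro
dissociation constants.  Free albumin is approximated by total albumin
(AF >> LT0), whereas AGP occupancy is resolved exactly through a
quadratic because GT0 is not large compared to the bound drug pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .parameters import DrugParameterSet, OralPKParameters

__all__ = ["ArterialState", "solve_arterial_equilibrium", "arterial_time_course"]


@dataclass(frozen=True)
class ArterialState:
    """Composition of the arterial plasma at total drug level ``LT0``."""

    GL0: float  #: globulin(AGP)-bound drug (nM)
    AL0: float  #: albumin-bound drug (nM)
    LF0: float  #: free drug, the in-vitro C_u,plasma (nM)
    GF0: float  #: free globulin (nM)
    LT0: float  #: total drug at which the state was computed (nM)

    @property
    def fu_in_vitro(self) -> float:
        """In-vitro fraction unbound, LF0/LT0."""
        if self.LT0 == 0:
            raise ZeroDivisionError("fraction unbound undefined at LT0 = 0")
        return self.LF0 / self.LT0


def solve_arterial_equilibrium(params: DrugParameterSet,
                               total_drug: float | None = None) -> ArterialState:
    """Solve the arterial binding equilibrium at a given total drug level.

    The globulin-bound pool solves the quadratic

        GL0 = 0.5*KG*(B - sqrt(B^2 - 4*GT0*LT0/KG^2)),
        B = 1 + AF/KA + (GT0 + LT0)/KG,

    using the in-vitro dissociation constants; the smaller root is the
    physical one (the larger exceeds min(GT0, LT0)).  Free and
    albumin-bound drug then follow from mass balance:

        LF0 = LT0 / (1 + AF/KA + GF0/KG)
        AL0 = (AF*LT0/KA) / (1 + AF/KA + GF0/KG)

    Parameters
    ----------
    params
        Drug parameter set supplying AF, GT0 and the in-vitro KDs.
    total_drug
        Total plasma drug concentration (nM).  Defaults to ``params.LT0``.
    """
    LT0 = params.LT0 if total_drug is None else float(total_drug)
    if LT0 < 0:
        raise ValueError(f"total drug concentration must be >= 0, got {LT0}")
    AF, GT0 = params.AF, params.GT0
    KA, KG = params.KA_in_vitro, params.KG_in_vitro
    if AF > 0 and KA <= 0:
        raise ZeroDivisionError("KA_in_vitro must be > 0 when albumin is present")
    if GT0 > 0 and KG <= 0:
        raise ZeroDivisionError("KG_in_vitro must be > 0 when globulin is present")

    alb = AF / KA if AF > 0 else 0.0

    if GT0 == 0 or LT0 == 0:
        # quadratic degenerates; no globulin-bound drug can form
        GL0 = 0.0
    else:
        B = 1.0 + alb + (GT0 + LT0) / KG
        disc = B * B - 4.0 * GT0 * LT0 / (KG * KG)
        assert disc >= 0.0, "negative discriminant for valid binding inputs"
        # smaller root 0.5*KG*(B - sqrt(disc)), written in conjugate form:
        # immune to cancellation when the bound pool is small
        GL0 = 2.0 * GT0 * LT0 / (KG * (B + math.sqrt(disc)))

    GF0 = GT0 - GL0
    denom = 1.0 + alb + (GF0 / KG if GT0 > 0 else 0.0)
    LF0 = LT0 / denom
    AL0 = alb * LT0 / denom

    assert 0.0 <= GL0 <= min(GT0, LT0) + 1e-9 * max(GT0, LT0, 1.0)
    assert abs(GL0 + AL0 + LF0 - LT0) <= 1e-9 * max(LT0, 1.0), "mass balance"
    return ArterialState(GL0=GL0, AL0=AL0, LF0=LF0, GF0=GF0, LT0=LT0)


def arterial_time_course(params: DrugParameterSet, pk: OralPKParameters,
                         t: float) -> ArterialState:
    """Arterial state at time ``t`` (min) after a single oral dose.

    The total plasma level follows the one-compartment Bateman input;
    the binding equilibrium is re-solved at that level (quasi-static
    arterial compartment).
    """
    from .nonsteady import oral_plasma_concentration  # local: avoid cycle

    return solve_arterial_equilibrium(params, oral_plasma_concentration(pk, t))
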