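"""Non-steady-state simulation of a single oral dose.

The systemic plasma drug level follows a one-compartment first-order
absorption/elimination (Bateman) input.  The arterial binding variables
are algebraic (quasi-equilibrium) driving functions of that input, and
seven coupled ODEs describe the brain capillary (GL, AL, LF, GF) and
brain (LM, PL, PF) compartments.  The rate constants span roughly six
orders of magnitude (0.0027 to 6,000 min^-1), so a stiff integrator is
required.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .parameters import DrugParameterSet, OralPKParameters
from .plasma_binding import ArterialState, solve_arterial_equilibrium

__all__ = [
    "TimeCourse",
    "AUCSummary",
    "oral_plasma_concentration",
    "simulate_oral",
    "auc_trapezoid",
    "summarize_auc",
    "capillary_brain_rhs",
]

#: order of the ODE state vector
STATE_NAMES = ("GL", "AL", "LF", "GF", "LM", "PL", "PF")

#: default integration tolerances (stiff BDF)
RTOL = 1e-8
ATOL = 1e-10  # nM


def oral_plasma_concentration(pk: OralPKParameters, t):
    """Total plasma drug concentration (nM) at time ``t`` (min) post-dose.

    Bateman function: ``b*s*k / (V*(k-d)) * (exp(-d*t) - exp(-k*t))``.
    Accepts scalars or arrays.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    amp = pk.b * pk.s * pk.k / (pk.V * (pk.k - pk.d))
    out = amp * (np.exp(-pk.d * t) - np.exp(-pk.k * t))
    return float(out) if out.ndim == 0 else out


def capillary_brain_rhs(y, arterial: ArterialState,
                        p: DrugParameterSet) -> np.ndarray:
    """Right-hand sides of the seven capillary/brain ODEs.

    ``y`` is ordered as :data:`STATE_NAMES`.  The BBB exchange terms
    carry the volume ratios as written in the model (efflux into the
    capillary scaled by VT/VP, influx into brain by VP/VT) so that
    transport is expressed per-compartment volume.
    """
    GL, AL, LF, GF, LM, PL, PF = y
    dGL = p.k10 * arterial.GL0 + p.k2 * LF * GF - p.k1 * GL - p.k10 * GL
    dAL = p.k10 * arterial.AL0 + p.k8 * p.AF * LF - p.k7 * AL - p.k10 * AL
    dLF = (p.k10 * arterial.LF0 + p.k1 * GL + p.k7 * AL
           + p.k4 * LM * (p.VT / p.VP)
           - p.k2 * LF * GF - p.k8 * p.AF * LF - p.k3 * LF - p.k10 * LF)
    dGF = p.k10 * arterial.GF0 + p.k1 * GL - p.k2 * LF * GF - p.k10 * GF
    dLM = (p.k3 * LF * (p.VP / p.VT) - (p.k4 + p.k9) * LM
           - p.k5 * LM * PF + p.k6 * PL)
    dPL = p.k5 * LM * PF - p.k6 * PL
    dPF = p.k6 * PL - p.k5 * LM * PF
    return np.array([dGL, dAL, dLF, dGF, dLM, dPL, dPF])


@dataclass(frozen=True)
class TimeCourse:
    """Trajectories of all model variables on a uniform time grid."""

    t: np.ndarray                 #: time grid (min), starting at 0
    variables: pd.DataFrame       #: one column per variable, indexed by t
    params: DrugParameterSet
    pk: OralPKParameters | None = None

    def __getitem__(self, name: str) -> np.ndarray:
        return self.variables[name].to_numpy()

    def kp_brain(self) -> np.ndarray:
        """Instantaneous K_p,brain(t) = (LM + PL)/LT0(t); NaN where LT0=0."""
        lt0 = self["LT0"]
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(lt0 > 0, (self["LM"] + self["PL"]) / lt0, np.nan)

    def to_csv(self, path, long_format: bool = False) -> None:
        df = self.variables.reset_index()
        if long_format:
            df = df.melt(id_vars="t", var_name="variable", value_name="conc_nM")
        df.to_csv(path, index=False)


@dataclass(frozen=True)
class AUCSummary:
    """Trapezoid areas under the concentration curves over [0, T]."""

    auc: dict[str, float] = field(default_factory=dict)  #: nM*min per variable
    T: float = 0.0

    @property
    def lf_over_lf0(self) -> float:
        """AUC ratio of capillary bioavailable to in-vitro free drug."""
        return self.auc["LF"] / self.auc["LF0"]

    @property
    def brain_over_plasma(self) -> float:
        """AUC ratio of total brain drug (LM+PL) to total plasma drug."""
        return (self.auc["LM"] + self.auc["PL"]) / self.auc["LT0"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"variable": list(self.auc),
                             "AUC_nM_min": list(self.auc.values())})


def _integrate(params: DrugParameterSet, lt0_of_t, horizon: float,
               grid_step: float, y0=None) -> TimeCourse:
    """Integrate the capillary/brain ODEs under an arbitrary LT0(t)."""
    if horizon <= 0 or grid_step <= 0:
        raise ValueError("horizon and grid_step must be > 0")
    t_eval = np.arange(0.0, horizon + 0.5 * grid_step, grid_step)
    t_eval[-1] = min(t_eval[-1], horizon)

    def rhs(t, y):
        art = solve_arterial_equilibrium(params, lt0_of_t(t))
        return capillary_brain_rhs(y, art, params)

    if y0 is None:
        y0 = np.array([0, 0, 0, params.GT0, 0, 0, params.PT], dtype=float)
    sol = solve_ivp(rhs, (0.0, float(horizon)), y0, method="BDF",
                    t_eval=t_eval, rtol=RTOL, atol=ATOL)
    if not sol.success:
        raise RuntimeError(
            f"stiff ODE integration failed: {sol.message} "
            f"(method=BDF, rtol={RTOL}, atol={ATOL})")

    lt0 = np.array([lt0_of_t(t) for t in sol.t])
    art = [solve_arterial_equilibrium(params, c) for c in lt0]
    cols = {
        "LT0": lt0,
        "GL0": np.array([a.GL0 for a in art]),
        "AL0": np.array([a.AL0 for a in art]),
        "LF0": np.array([a.LF0 for a in art]),
        "GF0": np.array([a.GF0 for a in art]),
    }
    for i, name in enumerate(STATE_NAMES):
        cols[name] = sol.y[i]
    df = pd.DataFrame(cols, index=pd.Index(sol.t, name="t"))
    return TimeCourse(t=sol.t, variables=df, params=params)


def simulate_oral(params: DrugParameterSet, pk: OralPKParameters,
                  horizon: float = 1440.0, grid_step: float = 1.0) -> TimeCourse:
    """Simulate all 12 variables after a single oral dose.

    Initial conditions: every drug species at 0, free globulin at GT0
    in both compartments, free tissue protein at PT.  Output is on a
    uniform grid of ``grid_step`` minutes over ``[0, horizon]``.
    """
    tc = _integrate(params, lambda t: oral_plasma_concentration(pk, t),
                    horizon, grid_step)
    return TimeCourse(t=tc.t, variables=tc.variables, params=params, pk=pk)


def simulate_constant_infusion(params: DrugParameterSet,
                               total_drug: float | None = None,
                               horizon: float = 1440.0,
                               grid_step: float = 1.0) -> TimeCourse:
    """Simulate with LT0 clamped constant (IV-infusion forcing).

    Starting from drug-free brain, the trajectories relax toward the
    closed-form steady state; used as a cross-validation oracle.
    """
    lt0 = params.LT0 if total_drug is None else float(total_drug)
    return _integrate(params, lambda t: lt0, horizon, grid_step)


def auc_trapezoid(t: np.ndarray, y: np.ndarray, T: float) -> float:
    """Composite trapezoid AUC of ``y(t)`` over ``[0, T]`` (nM*min)."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if T > t[-1] + 1e-9:
        raise ValueError(f"T={T} exceeds the stored grid end {t[-1]}")
    if not np.all(np.isfinite(y)):
        raise ValueError("concentration series contains non-finite values")
    mask = t <= T + 1e-9
    return float(np.trapezoid(y[mask], t[mask]))


def summarize_auc(tc: TimeCourse, T: float = 1440.0) -> AUCSummary:
    """AUCs of every variable plus the headline ratios over [0, T]."""
    order = ["LT0", "LF0", "GL0", "AL0", "LF", "GL", "AL", "LM", "PL"]
    auc = {v: auc_trapezoid(tc.t, tc[v], T) for v in order}
    auc["LM+PL"] = auc["LM"] + auc["PL"]
    return AUCSummary(auc=auc, T=float(T))
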