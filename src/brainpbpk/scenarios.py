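"""Scenario engine: named parameter overrides, batch tables, sweeps.

A scenario is a base drug (built-in name or parameter file) plus a
mapping of parameter overrides, run either at steady state or as an
oral-dose time course.  The packaged scenario files encode the full
published simulation sets for both drugs, so batch runs regenerate the
reference result tables cell by cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .parameters import (DrugParameterSet, OralPKParameters,
                         builtin_parameters, builtin_oral_pk, read_config,
                         SUPPORTED_DRUGS)
from .steady_state import SteadyStateSolution, solve_steady_state
from .nonsteady import AUCSummary, TimeCourse, simulate_oral, summarize_auc

__all__ = [
    "ScenarioSpec",
    "ScenarioReport",
    "run_scenario",
    "run_table",
    "parameter_sweep",
    "load_scenario_file",
    "packaged_scenarios",
    "pct_change",
    "fold",
]

_DRUG_FIELDS = {f.name for f in dc_fields(DrugParameterSet)} - {"label"}
_PK_FIELDS = {f.name for f in dc_fields(OralPKParameters)}

#: column order of the steady-state report, mirroring the published tables
TABLE_COLUMNS = ["GL0", "AL0", "LF0", "GL", "AL", "LF", "LM", "PL", "PF",
                 "Kp_brain"]


def pct_change(x: float, ref: float) -> float:
    """Percent change 100*(x - ref)/ref; NaN if the reference is zero."""
    return float("nan") if ref == 0 else 100.0 * (x - ref) / ref


def fold(x: float, ref: float) -> float:
    """Fold ratio x/ref; NaN if the reference is zero."""
    return float("nan") if ref == 0 else x / ref


@dataclass(frozen=True)
class ScenarioSpec:
    """Declarative scenario: base drug plus parameter overrides."""

    label: str
    base: str                      #: built-in drug name or parameter file path
    overrides: dict = field(default_factory=dict)
    mode: str = "steady"           #: "steady" or "oral"
    horizon: float = 1440.0        #: oral mode: simulated minutes
    grid_step: float = 1.0         #: oral mode: output grid (min)

    def __post_init__(self) -> None:
        if self.mode not in ("steady", "oral"):
            raise ValueError(f"mode must be 'steady' or 'oral', got {self.mode!r}")
        bad = set(self.overrides) - _DRUG_FIELDS - _PK_FIELDS
        if bad:
            raise KeyError(f"scenario {self.label!r}: unknown override "
                           f"key(s) {sorted(bad)}")

    def resolve(self) -> tuple[DrugParameterSet, OralPKParameters | None]:
        """Materialize the parameter set (and oral PK, if applicable)."""
        if self.base.strip().lower() in SUPPORTED_DRUGS:
            params = builtin_parameters(self.base)
        else:
            obj = read_config(self.base)
            if not isinstance(obj, DrugParameterSet):
                raise TypeError(f"{self.base} is not a drug parameter file")
            params = obj
        drug_over = {k: v for k, v in self.overrides.items() if k in _DRUG_FIELDS}
        params = params.with_overrides(label=self.label, **drug_over)
        pk = None
        if self.mode == "oral":
            pk = builtin_oral_pk(self.base) if self.base.strip().lower() in \
                SUPPORTED_DRUGS else None
            pk_over = {k: v for k, v in self.overrides.items() if k in _PK_FIELDS}
            if pk_over:
                base = pk or builtin_oral_pk("propranolol")
                pk = OralPKParameters(**{**{f: getattr(base, f) for f in
                                            _PK_FIELDS}, **pk_over})
        return params, pk


@dataclass(frozen=True)
class ScenarioReport:
    """Result of one scenario run, with the headline derived comparisons."""

    spec: ScenarioSpec
    steady: SteadyStateSolution | None = None
    auc: AUCSummary | None = None
    time_course: TimeCourse | None = None

    @property
    def pct_lf_vs_lf0(self) -> float:
        """Percent gain of capillary bioavailable drug over in-vitro free."""
        s = self._require_steady()
        return pct_change(s.LF, s.arterial.LF0)

    @property
    def pct_lm_vs_lf0(self) -> float:
        s = self._require_steady()
        return pct_change(s.LM, s.arterial.LF0)

    @property
    def fold_lf_vs_lf0(self) -> float:
        s = self._require_steady()
        return fold(s.LF, s.arterial.LF0)

    def compare(self, ref: "ScenarioReport") -> dict[str, float]:
        """Percent changes of LF and LM against a reference scenario."""
        s, r = self._require_steady(), ref._require_steady()
        return {"pct_LF": pct_change(s.LF, r.LF),
                "pct_LM": pct_change(s.LM, r.LM)}

    def _require_steady(self) -> SteadyStateSolution:
        if self.steady is None:
            raise ValueError(f"scenario {self.spec.label!r} has no "
                             "steady-state solution (oral mode)")
        return self.steady


def run_scenario(spec: ScenarioSpec) -> ScenarioReport:
    """Resolve and execute a single scenario."""
    params, pk = spec.resolve()
    if spec.mode == "steady":
        return ScenarioReport(spec=spec, steady=solve_steady_state(params))
    if pk is None:
        raise ValueError(f"scenario {spec.label!r}: oral mode requires "
                         "oral PK parameters")
    tc = simulate_oral(params, pk, horizon=spec.horizon,
                       grid_step=spec.grid_step)
    return ScenarioReport(spec=spec, time_course=tc,
                          auc=summarize_auc(tc, T=spec.horizon))


def run_table(specs: Sequence[ScenarioSpec]) -> pd.DataFrame:
    """Run a batch of steady-state scenarios into one report table.

    One row per scenario in the published column order; a scenario that
    fails is reported as a row with an ``error`` annotation rather than
    aborting the batch.
    """
    specs = list(specs)
    if not specs:
        raise ValueError("scenario list is empty")
    rows = []
    for spec in specs:
        row: dict = {"label": spec.label}
        try:
            rep = run_scenario(spec)
            row.update(rep.steady.as_row())
            row["error"] = ""
        except Exception as exc:  # noqa: BLE001 - per-row fault isolation
            row.update({c: float("nan") for c in TABLE_COLUMNS})
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows, columns=["label", *TABLE_COLUMNS, "error"])


def parameter_sweep(base: DrugParameterSet, param: str,
                    values: Iterable[float]) -> pd.DataFrame:
    """Steady-state solve for each value of one parameter.

    Returns columns (param, LM, PL, LF, Kp_brain).  Sweeping the brain
    tissue protein pool PT moves PL and K_p,brain but leaves the free
    brain drug LM untouched — free drug in brain is independent of
    tissue binding.
    """
    if param not in _DRUG_FIELDS:
        raise KeyError(f"unknown parameter {param!r}")
    rows = []
    for v in values:
        sol = solve_steady_state(base.with_overrides(**{param: v}))
        rows.append({param: v, "LM": sol.LM, "PL": sol.PL, "LF": sol.LF,
                     "Kp_brain": sol.Kp_brain})
    if not rows:
        raise ValueError("no sweep values supplied")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scenario files
# ---------------------------------------------------------------------------

def load_scenario_file(path: str | Path) -> list[ScenarioSpec]:
    """Load scenario specs from a YAML file.

    Layout: optional top-level ``base``/``mode`` defaults and a
    ``scenarios`` list of ``{label, overrides, ...}`` entries.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "scenarios" not in raw:
        raise ValueError(f"{path}: expected a mapping with a 'scenarios' list")
    default_base = raw.get("base", "")
    default_mode = raw.get("mode", "steady")
    out = []
    for entry in raw["scenarios"]:
        out.append(ScenarioSpec(
            label=str(entry["label"]),
            base=str(entry.get("base", default_base)),
            overrides=dict(entry.get("overrides") or {}),
            mode=str(entry.get("mode", default_mode)),
        ))
    return out


def packaged_scenarios(name: str) -> list[ScenarioSpec]:
    """Packaged simulation sets: ``propranolol`` (1-10 plus supplementary
    variants) or ``imipramine`` (11-20)."""
    fname = f"{name.strip().lower()}_simulations.yaml"
    ref = resources.files("brainpbpk.data") / "scenarios" / fname
    with resources.as_file(ref) as p:
        return load_scenario_file(p)
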