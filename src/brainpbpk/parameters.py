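"""Parameter containers, derivation rules, and config file I/O.

Global unit conventions (used everywhere in the package):

* concentrations in nM
* time in min, rate constants in min^-1
* bimolecular association rates in nM^-1 min^-1
  (1 nM^-1 min^-1 = 10^9/60 M^-1 s^-1)
* volumes in L/kg brain, dose in nmol/kg body weight
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields, replace, asdict
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "DrugParameterSet",
    "OralPKParameters",
    "builtin_parameters",
    "builtin_oral_pk",
    "derive_rate_constants",
    "read_config",
    "write_config",
    "SUPPORTED_DRUGS",
]

SUPPORTED_DRUGS = ("propranolol", "imipramine")

#: fields that must be strictly positive in a valid parameter set
_STRICTLY_POSITIVE = ("VP", "VT", "k3", "k10")


@dataclass(frozen=True)
class DrugParameterSet:
    """The 18 steady-state model parameters for one drug.

    The model describes a drug carried by plasma through the brain
    capillary bed while reversibly bound to albumin and to alpha-1-acid
    glycoprotein (AGP, "globulin" in the variable naming), exchanging
    across the blood-brain barrier (BBB), and binding to brain tissue
    proteins.  In-capillary binding kinetics (k1/k2 for AGP, k7/k8 for
    albumin) may differ from the in-vitro dissociation constants: that
    difference is what produces plasma-protein-mediated uptake (PMU).
    """

    LT0: float     #: total plasma drug concentration (nM)
    AF: float      #: total albumin concentration (nM); treated as constant
    GT0: float     #: total AGP ("globulin") concentration (nM)
    KA_in_vitro: float  #: KD drug-albumin in vitro (nM)
    KG_in_vitro: float  #: KD drug-AGP in vitro (nM)
    PT: float      #: total brain tissue binding protein (nM)
    VP: float      #: brain capillary plasma volume (L/kg)
    VT: float      #: brain extravascular volume (L/kg)
    k1: float      #: AGP dissociation rate in capillary (min^-1)
    k2: float      #: AGP association rate in capillary (nM^-1 min^-1)
    k3: float      #: BBB influx rate constant (min^-1)
    k4: float      #: BBB efflux rate constant (min^-1)
    k5: float      #: brain-protein association rate (nM^-1 min^-1)
    k6: float      #: brain-protein dissociation rate (min^-1)
    k7: float      #: albumin dissociation rate in capillary (min^-1)
    k8: float      #: albumin association rate in capillary (nM^-1 min^-1)
    k9: float      #: brain metabolism rate constant (min^-1)
    k10: float     #: capillary plasma flow rate constant (min^-1)
    label: str = ""

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "label":
                continue
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)):
                raise TypeError(f"parameter {f.name} must be numeric, got {v!r}")
            if v < 0:
                raise ValueError(f"parameter {f.name} must be >= 0, got {v}")
        for name in _STRICTLY_POSITIVE:
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be > 0")

    # -- derived dissociation constants ------------------------------------
    @property
    def KG_in_vivo(self) -> float:
        """In-capillary KD of the drug-AGP complex, k1/k2 (nM)."""
        if self.k2 <= 0:
            raise ValueError("KG_in_vivo undefined: k2 is zero")
        return self.k1 / self.k2

    @property
    def KA_in_vivo(self) -> float:
        """In-capillary KD of the drug-albumin complex, k7/k8 (nM)."""
        if self.k8 <= 0:
            raise ValueError("KA_in_vivo undefined: k8 is zero")
        return self.k7 / self.k8

    @property
    def KP(self) -> float:
        """KD of drug binding to brain tissue protein, k6/k5 (nM)."""
        if self.k5 <= 0:
            raise ValueError("KP undefined: k5 is zero")
        return self.k6 / self.k5

    def with_overrides(self, **overrides: float) -> "DrugParameterSet":
        """Return a copy with the named parameters replaced (re-validated)."""
        bad = [k for k in overrides if k not in {f.name for f in fields(self)}]
        if bad:
            raise KeyError(f"unknown parameter(s) {bad}; valid names are "
                           f"{sorted(f.name for f in fields(self))}")
        return replace(self, **overrides)


@dataclass(frozen=True)
class OralPKParameters:
    """One-compartment oral absorption/elimination parameters.

    The systemic plasma level after a single oral dose follows the
    Bateman function C(t) = b*s*k / (V*(k-d)) * (exp(-d*t) - exp(-k*t)).
    """

    b: float  #: fractional oral bioavailability (0, 1]
    s: float  #: dose (nmol/kg)
    k: float  #: first-order absorption rate constant (min^-1)
    d: float  #: first-order elimination rate constant (min^-1)
    V: float  #: systemic volume of distribution (L/kg)

    def __post_init__(self) -> None:
        if not 0 < self.b <= 1:
            raise ValueError(f"b must be in (0, 1], got {self.b}")
        if self.s <= 0 or self.V <= 0:
            raise ValueError("s and V must be > 0")
        if self.k <= 0 or self.d <= 0:
            raise ValueError("k and d must be > 0")
        if self.k == self.d:
            raise ValueError("absorption and elimination rates must differ "
                             "(k == d is the degenerate flip-flop case)")


def derive_rate_constants(
    KG_in_vivo: float,
    k2: float,
    KA_in_vivo: float,
    k8: float,
    PS_over_F: float,
    k10: float,
    VP: float,
    VT: float,
) -> tuple[float, float, float, float]:
    """Derive (k1, k7, k3, k4) from measurable quantities.

    k1 = k2 * KG_in_vivo and k7 = k8 * KA_in_vivo convert in-capillary
    dissociation constants into off-rates given the association rates.
    k3 = (PS/F) * k10 converts the permeability-surface-area to flow
    ratio into the influx rate constant, and k4 = k3 * VP/VT assumes
    symmetric passive transport across the BBB.
    """
    vals = dict(KG_in_vivo=KG_in_vivo, k2=k2, KA_in_vivo=KA_in_vivo, k8=k8,
                PS_over_F=PS_over_F, k10=k10, VP=VP, VT=VT)
    for name, v in vals.items():
        if v <= 0:
            raise ValueError(f"{name} must be > 0, got {v}")
    k1 = k2 * KG_in_vivo
    k7 = k8 * KA_in_vivo
    k3 = PS_over_F * k10
    k4 = k3 * (VP / VT)
    return k1, k7, k3, k4


# ---------------------------------------------------------------------------
# built-in parameter sets
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("brainpbpk.data") / name


def builtin_parameters(drug_name: str) -> DrugParameterSet:
    """Basal parameter set for one of the two packaged drugs.

    Propranolol shows enhanced dissociation from AGP only (in-vivo KG of
    19 uM versus 3.3 uM in vitro); imipramine from both AGP (90 uM vs
    1.2 uM) and albumin (>= 1,000 uM vs 42 uM).
    """
    name = drug_name.strip().lower()
    if name not in SUPPORTED_DRUGS:
        raise ValueError(
            f"unknown drug {drug_name!r}; supported drugs are "
            f"{', '.join(SUPPORTED_DRUGS)}"
        )
    with resources.as_file(_data_path(f"{name}.json")) as p:
        return read_config(p)


def builtin_oral_pk(drug_name: str = "propranolol") -> OralPKParameters:
    """Oral-dose PK parameters (80 mg oral propranolol in humans).

    Only propranolol ships with an oral PK component.
    """
    name = drug_name.strip().lower()
    if name != "propranolol":
        raise ValueError(
            f"no oral PK parameters available for {drug_name!r}; "
            "only propranolol has a packaged oral-dose parameter set"
        )
    with resources.as_file(_data_path("propranolol.json")) as p:
        raw = json.loads(Path(p).read_text())
    return OralPKParameters(**{k: raw[k] for k in ("b", "s", "k", "d", "V")})


# ---------------------------------------------------------------------------
# config file I/O
# ---------------------------------------------------------------------------

_DRUG_KEYS = [f.name for f in fields(DrugParameterSet) if f.name != "label"]
_PK_KEYS = [f.name for f in fields(OralPKParameters)]


def _parse_mapping(raw: Mapping, path: Path) -> DrugParameterSet | OralPKParameters:
    if not isinstance(raw, Mapping):
        raise ValueError(f"{path}: expected a flat key/value mapping")
    keys = set(raw)
    if keys.issuperset(_DRUG_KEYS):
        extra = keys - set(_DRUG_KEYS) - set(_PK_KEYS) - {"label"}
        if extra:
            raise ValueError(f"{path}: unrecognized key(s) {sorted(extra)}")
        kwargs = {k: raw[k] for k in _DRUG_KEYS}
        return DrugParameterSet(label=str(raw.get("label", path.stem)), **kwargs)
    if keys.issuperset(_PK_KEYS) and not keys & set(_DRUG_KEYS):
        return OralPKParameters(**{k: raw[k] for k in _PK_KEYS})
    missing = sorted(set(_DRUG_KEYS) - keys)
    raise ValueError(f"{path}: missing required parameter key(s) {missing}")


def read_config(path: str | Path) -> DrugParameterSet | OralPKParameters:
    """Read a flat JSON or YAML parameter file.

    A file with all 18 steady-state keys (optionally plus the 5 oral-PK
    keys, which are ignored here) parses as a :class:`DrugParameterSet`;
    a file with exactly the 5 oral-PK keys as :class:`OralPKParameters`.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    return _parse_mapping(raw, path)


def write_config(params: DrugParameterSet | OralPKParameters,
                 path: str | Path) -> None:
    """Write a parameter set to a flat JSON or YAML file (round-trip safe)."""
    path = Path(path)
    payload = asdict(params)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=2) + "\n")
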