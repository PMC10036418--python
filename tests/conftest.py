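"""Shared fixtures: built-in drugs, oral PK, random valid parameter draws."""

import numpy as np
import pytest

from brainpbpk import (builtin_parameters, builtin_oral_pk, DrugParameterSet)


@pytest.fixture(scope="session")
def propranolol() -> DrugParameterSet:
    return builtin_parameters("propranolol")


@pytest.fixture(scope="session")
def imipramine() -> DrugParameterSet:
    return builtin_parameters("imipramine")


@pytest.fixture(scope="session")
def oral_pk():
    return builtin_oral_pk("propranolol")


def draw_parameter_set(rng: np.random.Generator,
                       allow_metabolism: bool = True) -> DrugParameterSet:
    """One random physiologically plausible parameter set (log-uniform)."""
    def lu(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    return DrugParameterSet(
        LT0=lu(1, 1e3), AF=lu(1e4, 1e6), GT0=lu(1e3, 1e5),
        KA_in_vitro=lu(1e4, 1e6), KG_in_vitro=lu(3e2, 1e5),
        PT=lu(1e2, 1e4), VP=lu(0.005, 0.02), VT=lu(0.4, 1.0),
        k1=lu(10, 1e4), k2=lu(1e-3, 0.6), k3=lu(5, 300), k4=lu(0.1, 10),
        k5=lu(1e-4, 0.1), k6=lu(0.05, 10), k7=lu(50, 1e4),
        k8=lu(1e-3, 0.6),
        k9=lu(0.1, 6) if (allow_metabolism and rng.random() < 0.3) else 0.0,
        k10=lu(6, 120), label="random")


def assert_printed(value: float, printed: str, units: float = 1.0) -> None:
    """Assert agreement with a printed table cell to ``units`` of its
    last printed digit (e.g. "20.6" -> +/-0.1, "959" -> +/-1)."""
    clean = printed.replace(",", "")
    decimals = len(clean.split(".")[1]) if "." in clean else 0
    tol = units * 10.0 ** (-decimals)
    assert abs(value - float(clean)) <= tol + 1e-12, (
        f"{value!r} not within {tol} of printed {printed!r}")
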