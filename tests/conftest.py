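"""Shared fixtures and independent numerical oracles.

The oracle functions minimise the RMSD objectives by bounded scalar search
over their directly-summed definitions; they never touch the closed-form
code paths they are used to check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from vibscale.dataset import FrequencyPair, PairTable


def make_table(nu_calc, nu_exp, method="test") -> PairTable:
    pairs = [
        FrequencyPair(nu_calc=float(c), nu_exp=float(e),
                      molecule_id=f"m{i}", method=method)
        for i, (c, e) in enumerate(zip(nu_calc, nu_exp))
    ]
    return PairTable(method=method, pairs=pairs)


def armsd_direct(s: float, nu_calc, nu_exp) -> float:
    """aRMSD by direct summation (oracle)."""
    return math.sqrt(
        math.fsum((s * c - e) ** 2 for c, e in zip(nu_calc, nu_exp))
        / len(nu_calc)
    )


def rrmsd_direct(s: float, nu_calc, nu_exp) -> float:
    """rRMSD by direct summation (oracle)."""
    return math.sqrt(
        math.fsum((s * c / e - 1.0) ** 2 for c, e in zip(nu_calc, nu_exp))
        / len(nu_calc)
    )


def numeric_s_abs(nu_calc, nu_exp, lo=0.5, hi=1.5) -> float:
    """Scalar minimisation of the aRMSD (oracle for the closed form)."""
    res = minimize_scalar(
        lambda s: armsd_direct(s, nu_calc, nu_exp) ** 2,
        bounds=(lo, hi), method="bounded", options={"xatol": 1e-13},
    )
    return float(res.x)


def numeric_s_rel(nu_calc, nu_exp, lo=0.5, hi=1.5) -> float:
    """Scalar minimisation of the rRMSD (oracle for the closed form)."""
    res = minimize_scalar(
        lambda s: rrmsd_direct(s, nu_calc, nu_exp) ** 2,
        bounds=(lo, hi), method="bounded", options={"xatol": 1e-13},
    )
    return float(res.x)


def random_table(rng: np.random.Generator, n: int | None = None) -> PairTable:
    """Random pair table with wavenumber-like magnitudes and mild scatter."""
    if n is None:
        n = int(rng.integers(1, 200))
    nu_calc = rng.uniform(100.0, 4000.0, size=n)
    s = rng.uniform(0.8, 1.1)
    nu_exp = np.maximum(
        s * nu_calc + rng.normal(0.0, 25.0, size=n), 1.0
    )
    return make_table(nu_calc, nu_exp)


@pytest.fixture
def three_pair_table() -> PairTable:
    return make_table([1000.0, 2000.0, 3000.0], [980.0, 1880.0, 2850.0])


@pytest.fixture
def exact_table() -> PairTable:
    """nu_exp = 0.95 * nu_calc exactly."""
    nu_calc = [500.0, 1000.0, 1500.0, 3000.0]
    return make_table(nu_calc, [0.95 * c for c in nu_calc])
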