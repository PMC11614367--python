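"""Closed-form least-squares scale factors with maximum-likelihood errors.

A single multiplicative factor s maps computed harmonic wavenumbers onto
experimental fundamentals, s * nu_calc ~= nu_exp.  Two variants are fitted:

* absolute scaling minimises the absolute root-mean-square deviation

      aRMSD^2 = (1/N) sum_i (s * nu_calc_i - nu_exp_i)^2            [cm^-2]

* relative scaling minimises the relative deviation

      rRMSD^2 = (1/N) sum_i (s * nu_calc_i / nu_exp_i - 1)^2   [dimensionless]

Both are one-parameter regressions through the origin, y_i ~ s * x_i, with
x_i = nu_calc_i, y_i = nu_exp_i for the absolute case and
x_i = nu_calc_i / nu_exp_i, y_i = 1 for the relative case.  The solution is
closed-form,

      s_min   = S_xy / S_xx,      S_xy = sum x_i y_i,  S_xx = sum x_i^2,
      sigma0  = RMSD at s_min,
      sigma_s = sigma0 / sqrt(S_xx),

where sigma_s is the 1-sigma maximum-likelihood uncertainty of s (the
curvature of the quadratic objective).  Sums are accumulated with
compensated summation (math.fsum): nu^2 terms reach ~1e7 cm^-2 and naive
accumulation over ~1e4 pairs loses digits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .dataset import PairTable
from .errors import DegenerateInputError, EmptyDatasetError

logger = logging.getLogger(__name__)

__all__ = [
    "GenericLsqResult",
    "ScaleFactorFit",
    "lsq_scale",
    "fit_absolute",
    "fit_relative",
    "evaluate_armsd",
    "evaluate_rrmsd",
    "format_fit",
]


@dataclass(frozen=True)
class GenericLsqResult:
    """Solution of the one-parameter regression y ~ s*x through the origin.

    Attributes
    ----------
    s_min : float
        Optimal scale, S_xy / S_xx.
    sigma0 : float
        Per-point residual scale: the RMSD at the optimum.
    sigma_s : float
        1-sigma uncertainty of the scale, sigma0 / sqrt(S_xx).
    s_xx, s_xy, s_yy : float
        The accumulated sums (sum x^2, sum x*y, sum y^2).
    n : int
        Number of data points.
    """

    s_min: float
    sigma0: float
    sigma_s: float
    s_xx: float
    s_xy: float
    s_yy: float
    n: int


@dataclass(frozen=True)
class ScaleFactorFit:
    """A fitted scale factor with its accuracy metrics.

    ``armsd`` is in cm^-1, ``rrmsd`` dimensionless.  For the absolute
    objective ``armsd`` is the minimised value and ``rrmsd`` the
    cross-evaluated one; vice versa for the relative objective.
    """

    objective: Literal["absolute", "relative"]
    s: float
    sigma: float
    armsd: float
    rrmsd: float
    n_total: int
    method: str


def lsq_scale(x: Sequence[float], y: Sequence[float]) -> GenericLsqResult:
    """Fit y ~ s*x by least squares; closed form with ML uncertainty.

    Raises
    ------
    DegenerateInputError
        On length mismatch, empty input, or sum(x^2) == 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise DegenerateInputError(
            f"x and y must be 1-d of equal length, got {x.shape} and {y.shape}"
        )
    n = x.size
    if n == 0:
        raise DegenerateInputError("empty input")

    s_xx = math.fsum(x * x)
    s_xy = math.fsum(x * y)
    s_yy = math.fsum(y * y)
    if s_xx <= 0.0:
        raise DegenerateInputError("sum(x^2) is zero; scale is undefined")

    s_min = s_xy / s_xx
    # Residual form of the optimal RMSD: algebraically (S_yy - S_xy^2/S_xx)/n
    # but free of the catastrophic cancellation between the two large sums.
    sigma0_sq = max(0.0, math.fsum((s_min * x - y) ** 2) / n)
    sigma0 = math.sqrt(sigma0_sq)
    sigma_s = sigma0 / math.sqrt(s_xx)
    return GenericLsqResult(
        s_min=s_min, sigma0=sigma0, sigma_s=sigma_s,
        s_xx=s_xx, s_xy=s_xy, s_yy=s_yy, n=n,
    )


def _require_nonempty(table: PairTable) -> None:
    if table.n_total == 0:
        raise EmptyDatasetError("pair table is empty")


def fit_absolute(table: PairTable) -> ScaleFactorFit:
    """Absolute scale factor: minimise the aRMSD over the pair table."""
    _require_nonempty(table)
    res = lsq_scale(table.nu_calc, table.nu_exp)
    if res.n == 1:
        logger.warning(
            "fitting a single pair: sigma is 0 by construction, "
            "not a meaningful uncertainty"
        )
    s = res.s_min
    return ScaleFactorFit(
        objective="absolute",
        s=s,
        sigma=res.sigma_s,
        armsd=res.sigma0,
        rrmsd=evaluate_rrmsd(s, table),
        n_total=res.n,
        method=table.method,
    )


def fit_relative(table: PairTable) -> ScaleFactorFit:
    """Relative scale factor: minimise the rRMSD over the pair table."""
    _require_nonempty(table)
    nu_exp = table.nu_exp
    if np.any(nu_exp <= 0):
        raise DegenerateInputError("relative fit requires all nu_exp > 0")
    x = table.nu_calc / nu_exp
    res = lsq_scale(x, np.ones_like(x))
    if res.n == 1:
        logger.warning(
            "fitting a single pair: sigma is 0 by construction, "
            "not a meaningful uncertainty"
        )
    s = res.s_min
    return ScaleFactorFit(
        objective="relative",
        s=s,
        sigma=res.sigma_s,
        armsd=evaluate_armsd(s, table),
        rrmsd=res.sigma0,
        n_total=res.n,
        method=table.method,
    )


def evaluate_armsd(s: float, table: PairTable) -> float:
    """aRMSD (cm^-1) of the table scaled by an arbitrary factor s."""
    _require_nonempty(table)
    resid = s * table.nu_calc - table.nu_exp
    return math.sqrt(math.fsum(resid * resid) / table.n_total)


def evaluate_rrmsd(s: float, table: PairTable) -> float:
    """rRMSD (dimensionless) of the table scaled by an arbitrary factor s."""
    _require_nonempty(table)
    nu_exp = table.nu_exp
    if np.any(nu_exp <= 0):
        raise DegenerateInputError("rRMSD requires all nu_exp > 0")
    resid = s * table.nu_calc / nu_exp - 1.0
    return math.sqrt(math.fsum(resid * resid) / table.n_total)


def format_fit(fit: ScaleFactorFit) -> str:
    """Render a fit in the compact printed style, e.g. ``0.9688(3)``.

    The 1-sigma uncertainty is rounded to one significant digit and quoted
    in parentheses at the last decimal place of s; s is rounded to that
    same place.  A zero sigma (exact fit) renders as ``(0)`` at four
    decimals with a logged note.
    """
    s, sigma = fit.s, fit.sigma
    # sigma at float round-off level means the fit is exact; genuine
    # uncertainties in this domain are many orders of magnitude larger
    if sigma <= 1e-12 * max(1.0, abs(s)):
        logger.info("sigma = 0 indicates an exact fit; quoting 4 decimals")
        return f"{s:.4f}(0)"
    # position of the leading significant digit of sigma
    exponent = math.floor(math.log10(sigma))
    digit = round(sigma / 10.0 ** exponent)
    if digit == 10:  # e.g. 0.00095 -> 1e-3
        digit = 1
        exponent += 1
    decimals = max(0, -exponent)
    return f"{s:.{decimals}f}({digit:d})"
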