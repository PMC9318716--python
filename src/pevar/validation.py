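"""Statistical validation tools: z comparison of PE values and drift fits.

Once every PE value carries an uncertainty, two segments can be compared
with an ordinary two-sided z test, and a sequence of segment-wise PE
values can be tested against a smooth drift law by a weighted least-squares
fit whose minimized normalized residual sum is chi-square distributed when
the error bars are right.  The module is scale-agnostic: values and
uncertainties may be in nats or normalized by log(m!), as long as both are
on the same scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DriftFitResult",
    "z_test_pe",
    "quadratic_drift_fit",
    "linear_drift_fit",
    "chi2_3_pdf",
]


@dataclass(frozen=True)
class DriftFitResult:
    """Weighted least-squares fit of a polynomial drift law to PE values.

    ``s_min`` is the minimized sum of squared normalized residuals
    sum_k [(h_k - model(k)) / sigma_k]^2; under the null hypothesis that
    the sigmas are the true uncertainties and the drift law holds, it is
    chi-square distributed with ``nu`` = (#points - #coefficients) degrees
    of freedom, and ``p_tail`` is the corresponding upper-tail probability.
    For the linear law ``c_hat`` is identically zero.
    """

    a_hat: float
    b_hat: float
    c_hat: float
    s_min: float
    nu: int
    p_tail: float

    def __post_init__(self) -> None:
        if self.s_min < -1e-12:
            raise ValueError("minimized residual sum cannot be negative")


def z_test_pe(
    h1: float, sigma1: float, h2: float, sigma2: float
) -> tuple[float, float]:
    """Two-sided z test for the difference of two PE values.

    Returns ``(z, p)`` with ``z = (h2 - h1) / sqrt(sigma1^2 + sigma2^2)``
    and ``p`` the two-sided standard-normal tail probability.  The null
    hypothesis is that the difference between the two assessments is due
    to chance alone.
    """
    if sigma1 <= 0 or sigma2 <= 0:
        raise ValueError("uncertainties must be strictly positive")
    z = (h2 - h1) / math.hypot(sigma1, sigma2)
    p = 2.0 * stats.norm.sf(abs(z))
    return z, p


def _drift_fit(
    h: Sequence[float],
    sigma: Sequence[float],
    k: Optional[Sequence[float]],
    degree: int,
) -> DriftFitResult:
    h = np.asarray(h, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if h.ndim != 1 or h.shape != sigma.shape:
        raise ValueError("h and sigma must be 1-d and of equal length")
    if np.any(sigma <= 0):
        raise ValueError("all uncertainties must be strictly positive")
    npts = h.size
    ncoef = degree + 1
    if npts <= ncoef:
        raise ValueError(f"need more than {ncoef} points for a degree-{degree} fit")
    kk = np.arange(1, npts + 1, dtype=float) if k is None else np.asarray(k, float)
    design = np.vander(kk, ncoef, increasing=True)  # columns 1, k, k^2, ...
    w = 1.0 / sigma
    beta, *_ = np.linalg.lstsq(design * w[:, None], h * w, rcond=None)
    resid = (h - design @ beta) * w
    s_min = float(resid @ resid)
    nu = npts - ncoef
    coef = np.zeros(3)
    coef[:ncoef] = beta
    return DriftFitResult(
        a_hat=float(coef[0]),
        b_hat=float(coef[1]),
        c_hat=float(coef[2]),
        s_min=s_min,
        nu=nu,
        p_tail=float(stats.chi2.sf(s_min, nu)),
    )


def quadratic_drift_fit(
    h: Sequence[float],
    sigma: Sequence[float],
    k: Optional[Sequence[float]] = None,
) -> DriftFitResult:
    """Fit ``a + b k + c k^2`` to PE values weighted by their uncertainties.

    The model is linear in (a, b, c), so the minimum is found in closed
    form by weighted linear least squares.  With the canonical six points
    ``k = 1..6`` the fit leaves nu = 3 degrees of freedom and ``s_min``
    is referred to the chi-square(3) distribution.
    """
    return _drift_fit(h, sigma, k, degree=2)


def linear_drift_fit(
    h: Sequence[float],
    sigma: Sequence[float],
    k: Optional[Sequence[float]] = None,
) -> DriftFitResult:
    """Fit the linear drift law ``a + b k``; with six points nu = 4."""
    return _drift_fit(h, sigma, k, degree=1)


def chi2_3_pdf(x) -> np.ndarray | float:
    """Probability density of the chi-square distribution with 3 degrees of
    freedom: f(x) = sqrt(x / (2 pi)) * exp(-x / 2) for x >= 0."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("chi-square density is defined for x >= 0 only")
    out = np.sqrt(arr / (2.0 * np.pi)) * np.exp(-arr / 2.0)
    return out if arr.ndim else float(out)
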