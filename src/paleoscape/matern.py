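"""Matérn correlation family for spatially structured random effects.

The Matérn family is the standard two-parameter correlation model in
geostatistics: smoothness ``nu`` controls mean-square differentiability of
the field, range ``rho`` sets the distance scale of decorrelation.
``nu = 0.5`` reduces to the exponential model ``exp(-d/rho)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, kv

__all__ = ["MaternParams", "matern_correlation", "matern_correlation_matrix"]


@dataclass(frozen=True)
class MaternParams:
    """Parameters of a Matérn covariance: smoothness, range, marginal variance.

    ``sigma2`` may be 0 (a boundary fit with no spatial signal); ``nu`` and
    ``rho`` must be strictly positive.
    """

    nu: float
    rho: float
    sigma2: float

    def __post_init__(self) -> None:
        if not (self.nu > 0):
            raise ValueError(f"nu must be > 0, got {self.nu}")
        if not (self.rho > 0):
            raise ValueError(f"rho must be > 0, got {self.rho}")
        if self.sigma2 < 0:
            raise ValueError(f"sigma2 must be >= 0, got {self.sigma2}")


def matern_correlation(d, nu: float, rho: float):
    """Matérn correlation C(d) = 2^(1-nu)/Gamma(nu) * (d/rho)^nu * K_nu(d/rho).

    Parameters
    ----------
    d : array_like
        Distances, >= 0 (same units as ``rho``).
    nu : float
        Smoothness, > 0.
    rho : float
        Range, > 0.

    Returns
    -------
    ndarray or float
        Correlations in [0, 1]; C(0) = 1 by the limit.
    """
    if nu <= 0 or rho <= 0:
        raise ValueError("nu and rho must be positive")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    x = d / rho
    out = np.ones_like(x)
    # below ~1e-8 the analytic limit C -> 1 is exact to double precision
    pos = x > 1e-8
    xp = x[pos]
    # log-scale product avoids overflow of Gamma(nu) against K_nu underflow
    with np.errstate(over="ignore", under="ignore"):
        bess = kv(nu, xp)
        safe = np.where(bess > 0, bess, 1.0)
        logc = (1.0 - nu) * np.log(2.0) - gammaln(nu) + nu * np.log(xp) + np.log(safe)
        val = np.where(bess > 0, np.exp(logc), 0.0)
    out[pos] = np.clip(val, 0.0, 1.0)
    if out.ndim == 0:
        return float(out)
    return out


def matern_correlation_matrix(coords: np.ndarray, nu: float, rho: float) -> np.ndarray:
    """Dense Matérn correlation matrix for points ``coords`` (n, 2).

    Distances are Euclidean in the coordinate units (degrees by default in
    this package, matching the convention of computing distances directly on
    longitude/latitude).
    """
    coords = np.asarray(coords, dtype=float)
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    return matern_correlation(d, nu, rho)
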