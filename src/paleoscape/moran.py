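"""Spatial cluster/outlier QC: Global and Anselin Local Moran's I.

Per time bin, δ15N values at (jittered) sample points are tested for
spatial autocorrelation with Global Moran's I and classified point-by-point
with Local Moran's I (LISA).  Weights are inverse Euclidean distance on
(lon, lat) degrees, row-standardized.  Local inference uses conditional
permutation (hold the value at i, permute the rest), with
Benjamini–Hochberg FDR control over the per-point p-values; spatial
outliers (negative local I, significant after FDR) are removed before
site aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SpatialWeightMatrix",
    "LocalMoranResult",
    "GlobalMoranResult",
    "jitter_coincident",
    "build_inverse_distance_weights",
    "local_moran",
    "global_moran",
    "fdr_adjust",
    "classify_and_filter",
    "CLUSTER_LABELS",
]

HIGH_CLUSTER = "HIGH_CLUSTER"
LOW_CLUSTER = "LOW_CLUSTER"
HIGH_LOW_OUTLIER = "HIGH_LOW_OUTLIER"
LOW_HIGH_OUTLIER = "LOW_HIGH_OUTLIER"
NOT_SIGNIFICANT = "NOT_SIGNIFICANT"
CLUSTER_LABELS = (HIGH_CLUSTER, LOW_CLUSTER, HIGH_LOW_OUTLIER, LOW_HIGH_OUTLIER, NOT_SIGNIFICANT)

_OUTLIER_LABELS = {HIGH_LOW_OUTLIER, LOW_HIGH_OUTLIER}


@dataclass
class SpatialWeightMatrix:
    n: int
    weights: np.ndarray
    row_standardized: bool
    jitter_applied: bool = False
    jittered_coords: np.ndarray | None = None


@dataclass
class LocalMoranResult:
    Ii: np.ndarray
    z_score: np.ndarray          # permutation-based standardized deviate
    z_analytic: np.ndarray       # analytic (total-randomization moments) deviate
    p_raw: np.ndarray
    p_fdr: np.ndarray
    labels: list[str] | None = None


@dataclass
class GlobalMoranResult:
    I: float
    expected: float
    z_score: float
    p_value: float


def jitter_coincident(
    coords: np.ndarray, magnitude: float = 0.1, seed: int = 0
) -> np.ndarray:
    """Displace coincident points by uniform offsets in a centered box.

    Points identical to within 1e-9 degrees form a coincident group; every
    member after the first receives an independent uniform offset in
    [-magnitude/2, +magnitude/2] on each axis.  Non-coincident points are
    untouched.  Deterministic given ``seed``.
    """
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    rng = np.random.default_rng(seed)
    out = coords.copy()
    key = np.round(coords / 1e-9).astype(np.int64)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    for g in np.flatnonzero(counts > 1):
        members = np.flatnonzero(inv == g)
        for i in members[1:]:
            out[i] = coords[i] + rng.uniform(-magnitude / 2, magnitude / 2, size=2)
    return out


def build_inverse_distance_weights(
    coords: np.ndarray, row_standardize: bool = True
) -> SpatialWeightMatrix:
    """Inverse Euclidean-distance weights w_ij = 1/d_ij, zero diagonal.

    Distances are computed directly on (lon, lat) in degrees.  Raises if
    any two distinct points coincide — jitter first.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    off = ~np.eye(n, dtype=bool)
    if np.any(d[off] == 0):
        raise ValueError(
            "zero distance between distinct points: apply jitter_coincident first"
        )
    w = np.zeros_like(d)
    w[off] = 1.0 / d[off]
    if row_standardize:
        rs = w.sum(axis=1, keepdims=True)
        rs[rs == 0] = 1.0
        w = w / rs
    return SpatialWeightMatrix(n=n, weights=w, row_standardized=row_standardize)


def _moran_terms(values: np.ndarray):
    x = np.asarray(values, dtype=float)
    z = x - x.mean()
    m2 = (z**2).sum() / len(x)   # denominator n, so sum_i Ii = n * I_global
    # constant input up to floating residue counts as zero variance
    if m2 < 1e-24 * (1.0 + x.mean() ** 2):
        m2 = 0.0
    return z, m2


def local_moran(
    values: np.ndarray,
    W: SpatialWeightMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> LocalMoranResult:
    """Anselin's Local Moran's I with conditional-permutation inference.

    Ii = (z_i / m2) * sum_j w_ij z_j with z centred values and
    m2 = sum z^2 / n.  For each point the remaining values are permuted
    across the other locations ``n_perm`` times; the two-sided pseudo
    p-value is (#{|I*| >= |Ii|} + 1) / (n_perm + 1).  Constant input gives
    Ii = 0 and p = 1 everywhere.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("local Moran's I needs n >= 4")
    if not W.row_standardized:
        raise ValueError("weights must be row-standardized")
    z, m2 = _moran_terms(x)
    if m2 == 0:
        zeros = np.zeros(n)
        return LocalMoranResult(zeros, zeros.copy(), zeros.copy(), np.ones(n), np.ones(n))

    w = W.weights
    Ii = (z / m2) * (w @ z)

    rng = np.random.default_rng(seed)
    p_raw = np.empty(n)
    z_perm = np.empty(n)
    others_idx = np.arange(n - 1)
    for i in range(n):
        zi_others = np.delete(z, i)
        wi = np.delete(w[i], i)
        idx = np.tile(others_idx, (n_perm, 1))
        idx = rng.permuted(idx, axis=1)
        lag = zi_others[idx] @ wi
        Istar = (z[i] / m2) * lag
        p_raw[i] = (np.count_nonzero(np.abs(Istar) >= abs(Ii[i])) + 1) / (n_perm + 1)
        sd = Istar.std(ddof=1)
        z_perm[i] = (Ii[i] - Istar.mean()) / sd if sd > 0 else 0.0

    # analytic deviate under total randomization (reported for comparison)
    wi2 = (w**2).sum(axis=1) - np.diag(w) ** 2
    b2 = n * (z**4).sum() / (z**2).sum() ** 2
    e_i = -(w.sum(axis=1) - np.diag(w)) / (n - 1)
    var_i = wi2 * (n - b2) / (n - 1) - e_i**2
    var_i = np.clip(var_i, 1e-300, None)
    z_analytic = (Ii - e_i) / np.sqrt(var_i)

    p_fdr = fdr_adjust(p_raw)
    return LocalMoranResult(Ii, z_perm, z_analytic, p_raw, p_fdr)


def global_moran(values: np.ndarray, W: SpatialWeightMatrix) -> GlobalMoranResult:
    """Global Moran's I with z-score under the randomization assumption.

    I = (n/S0) * sum_ij w_ij z_i z_j / sum_i z_i^2.  Constant values give an
    undefined index, reported as NaN.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("global Moran's I needs n >= 4")
    z, _ = _moran_terms(x)
    denom = (z**2).sum()
    expected = -1.0 / (n - 1)
    if denom == 0:
        return GlobalMoranResult(np.nan, expected, np.nan, np.nan)
    w = W.weights
    S0 = w.sum()
    I = (n / S0) * (z @ w @ z) / denom

    S1 = 0.5 * ((w + w.T) ** 2).sum()
    S2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    b2 = n * (z**4).sum() / denom**2
    num = n * ((n**2 - 3 * n + 3) * S1 - n * S2 + 3 * S0**2) - b2 * (
        (n**2 - n) * S1 - 2 * n * S2 + 6 * S0**2
    )
    var = num / ((n - 1) * (n - 2) * (n - 3) * S0**2) - expected**2
    from scipy.stats import norm

    zsc = (I - expected) / np.sqrt(var)
    p = 2 * norm.sf(abs(zsc))
    return GlobalMoranResult(float(I), float(expected), float(zsc), float(p))


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, original order preserved."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def classify_and_filter(
    result: LocalMoranResult,
    values: np.ndarray,
    alpha: float = 0.05,
) -> tuple[list[str], np.ndarray]:
    """Label each point and return indices of non-outliers.

    Significant (p_fdr < alpha) positive local I is a cluster (high/low by
    the point's value vs the mean); significant negative local I is an
    outlier (a high value among low neighbours or vice versa).  The
    filtered set keeps everything not labelled an outlier.
    """
    x = np.asarray(values, dtype=float)
    xbar = x.mean()
    labels: list[str] = []
    for Ii, p, xi in zip(result.Ii, result.p_fdr, x):
        if p < alpha and Ii > 0:
            labels.append(HIGH_CLUSTER if xi > xbar else LOW_CLUSTER)
        elif p < alpha and Ii < 0:
            labels.append(HIGH_LOW_OUTLIER if xi > xbar else LOW_HIGH_OUTLIER)
        else:
            labels.append(NOT_SIGNIFICANT)
    result.labels = labels
    keep = np.array([lab not in _OUTLIER_LABELS for lab in labels])
    return labels, np.flatnonzero(keep)
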