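"""Two-step geostatistical mixed model for δ15N isoscapes.

Per time bin, samples are aggregated to site level (mean, variance, count
of δ15N).  Interpolation then proceeds in two steps:

1. **Dispersion model** — a Gamma GLMM for the per-site sample variances
   v_i ~ Gamma(shape k_i = (n_i - 1)/2, mean phi(s_i)), with
   log phi(s_i) = beta_d0 + u_d(s_i) + b_d,i, where u_d is a Matérn
   Gaussian process and b_d an iid site effect.  The shape follows from
   the exact sampling distribution of a normal-sample variance.  Fitted by
   Laplace-approximated restricted maximum likelihood (the intercept is
   integrated out with a flat prior alongside the latent field).

2. **Mean model** — a linear mixed model for site-mean δ15N,
   ybar_i = x_i' beta + u(s_i) + b_i + eps_i, with u ~ GP(0, sigma2_u *
   Matérn(nu, rho)), b iid N(0, sigma2_b), and eps_i ~ N(0, phi_hat_i /
   n_i) held fixed at the dispersion-model predictions.  Variance
   parameters by REML with beta profiled out by GLS.

Model comparison uses the conditional AIC: -2 * conditional log-likelihood
plus twice the effective degrees of freedom (trace of the hat matrix
mapping observations to conditional fitted values, plus one per estimated
covariance parameter).  Prediction surfaces follow the universal-kriging
form, with fixed-effect uncertainty included and residual sampling
variance excluded.

Distances are Euclidean on (lon, lat) degrees throughout, matching the
convention of computing the Matérn on raw coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy.optimize import minimize

from .matern import MaternParams, matern_correlation
from .rasters import ClimateRaster, sample_raster

__all__ = [
    "ModelSpec",
    "DispersionModelFit",
    "MeanModelFit",
    "IsoscapeRaster",
    "aggregate_by_site",
    "fit_dispersion_model",
    "predict_dispersion",
    "fit_mean_model",
    "caic",
    "enumerate_model_set",
    "select_best_model",
    "predict_isoscape",
    "predict_points",
    "predicted_vs_observed",
]

_LOGV_BOUNDS = (-20.0, 10.0)       # log variance components
_LOGRHO_BOUNDS = (np.log(1e-3), np.log(1e3))
_LOGNU_BOUNDS = (np.log(0.1), np.log(5.0))


# ---------------------------------------------------------------------------
# aggregation

def aggregate_by_site(
    samples: pd.DataFrame,
    bin_name: str | None = None,
    taxon_filter: str | None = None,
    lon_col: str = "longitude",
    lat_col: str = "latitude",
) -> pd.DataFrame:
    """Per-site mean, variance (n-1 denominator) and count of δ15N.

    Grouping key is (site_id, bin); coordinates are the per-site means of
    the (jittered) sample coordinates.  ``taxon_filter`` restricts to one
    taxon for species-specific isoscapes.  Variance is missing for
    single-observation sites.
    """
    df = samples
    if bin_name is not None:
        df = df[df["bin"] == bin_name]
    if taxon_filter is not None:
        df = df[df["taxon"] == taxon_filter]
    if len(df) == 0:
        raise ValueError("no samples left to aggregate")
    keys = ["site_id"] + (["bin"] if "bin" in df.columns else [])
    g = df.groupby(keys, sort=True)
    out = g.agg(
        lon=(lon_col, "mean"),
        lat=(lat_col, "mean"),
        n_obs=("d15N", "size"),
        mean_d15N=("d15N", "mean"),
        var_d15N=("d15N", lambda x: x.var(ddof=1) if len(x) > 1 else np.nan),
    ).reset_index()
    return out


# ---------------------------------------------------------------------------
# shared linear algebra

def _dist_matrix(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def _chol_solve(L: np.ndarray, b: np.ndarray) -> np.ndarray:
    return sla.cho_solve((L, True), b)


def _logdet_from_chol(L: np.ndarray) -> float:
    return 2.0 * float(np.log(np.diag(L)).sum())


def _re_cov(dist, sigma2_u, sigma2_b, rho, nu):
    """Covariance of the combined random effect u + b at the data sites."""
    C = matern_correlation(dist, nu, rho) if sigma2_u > 0 else np.zeros_like(dist)
    return sigma2_u * C + sigma2_b * np.eye(len(dist))


# ---------------------------------------------------------------------------
# dispersion model

@dataclass
class DispersionModelFit:
    """Gamma GLMM fit to per-site δ15N sample variances."""

    beta_d0: float
    beta_d0_se: float
    matern_d: MaternParams
    site_var_d: float
    loglik: float
    converged: bool
    predicted_phi: pd.Series          # per fitted site, response scale
    gamma_shape_rule: str = "k_i = (n_i - 1) / 2 (normal-sample variance)"
    # fitting internals used for spatial prediction at unseen sites
    _coords: np.ndarray | None = None
    _w_hat: np.ndarray | None = None


def _disp_inner(v, k, beta0, Sigma_inv, w_init, max_iter=100, tol=1e-10):
    """Newton maximization over the latent field w at fixed intercept.

    Returns (w_hat, H) with H = diag(W) + Sigma^-1 the negative Hessian of
    the joint density in w at the mode.
    """
    w = w_init.copy()

    def joint(w):
        eta = beta0 + w
        return float(np.sum(-k * eta - k * v * np.exp(-eta)) - 0.5 * w @ Sigma_inv @ w)

    J = joint(w)
    for _ in range(max_iter):
        eta = beta0 + w
        Wd = k * v * np.exp(-eta)            # -d2/d eta2 of the Gamma loglik
        grad = (-k + Wd) - Sigma_inv @ w
        H = np.diag(Wd) + Sigma_inv
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(H + 1e-8 * np.eye(len(w)), grad)
        t = 1.0
        for _ in range(30):
            w_new = w + t * step
            J_new = joint(w_new)
            if J_new >= J - 1e-12:
                break
            t /= 2
        w, J_prev, J = w_new, J, J_new
        if abs(J - J_prev) < tol * (1 + abs(J)):
            break
    eta = beta0 + w
    Wd = k * v * np.exp(-eta)
    return w, np.diag(Wd) + Sigma_inv


def fit_dispersion_model(
    aggregates: pd.DataFrame,
    seed: int = 0,
    fix_nu: float | None = None,
    n_starts: int = 3,
) -> DispersionModelFit:
    """Fit the Gamma dispersion GLMM by Laplace-approximated REML.

    Sites with at least two observations contribute their sample variance
    v_i with Gamma shape k_i = (n_i - 1)/2.  Estimation is restricted:
    covariance parameters (log sigma2_u, log sigma2_b, log rho[, log nu])
    are optimized against the Laplace marginal with the intercept
    integrated out alongside the latent field (the REML analogue), from
    ``n_starts`` seeded starts; the intercept is then estimated by
    maximizing the Laplace marginal at the restricted covariance
    estimates.  Its standard error comes from the joint (intercept, field)
    Hessian, so it reflects the spatial field's own uncertainty; it is
    conditional on the covariance estimates.
    """
    from scipy.special import gammaln

    sub = aggregates[(aggregates["n_obs"] >= 2) & aggregates["var_d15N"].notna()].copy()
    if len(sub) < 5:
        raise ValueError(
            f"dispersion model needs >= 5 sites with n_obs >= 2, got {len(sub)}"
        )
    v = np.maximum(sub["var_d15N"].to_numpy(dtype=float), 1e-8)
    k = (sub["n_obs"].to_numpy(dtype=float) - 1.0) / 2.0
    coords = sub[["lon", "lat"]].to_numpy(dtype=float)
    dist = _dist_matrix(coords)
    n = len(v)
    beta0_start = float(np.log(v.mean()))
    span = max(dist.max(), 1e-3)
    const = float(np.sum(k * np.log(k) + (k - 1) * np.log(v) - gammaln(k)))

    estimate_nu = fix_nu is None

    def unpack(theta):
        s2u, s2b, rho = np.exp(theta[0]), np.exp(theta[1]), np.exp(theta[2])
        nu = np.exp(theta[3]) if estimate_nu else fix_nu
        return s2u, s2b, rho, nu

    cache = {"w": np.zeros(n), "b0": beta0_start}

    def sigma_inv_for(s2u, s2b, rho, nu):
        Sigma = _re_cov(dist, s2u, s2b, rho, nu)
        Sigma[np.diag_indices(n)] += 1e-8
        L = sla.cholesky(Sigma, lower=True)
        return _chol_solve(L, np.eye(n)), L

    def joint_inner(Sigma_inv, b0, w, max_iter=100, tol=1e-10):
        """Newton over (b0, w) jointly; returns mode and joint Hessian."""
        def joint(b0, w):
            eta = b0 + w
            return float(np.sum(-k * eta - k * v * np.exp(-eta)) - 0.5 * w @ Sigma_inv @ w)

        J = joint(b0, w)
        for _ in range(max_iter):
            eta = b0 + w
            Wd = k * v * np.exp(-eta)
            g1 = -k + Wd
            grad = np.concatenate(([g1.sum()], g1 - Sigma_inv @ w))
            H = np.zeros((n + 1, n + 1))
            H[0, 0] = Wd.sum()
            H[0, 1:] = Wd
            H[1:, 0] = Wd
            H[1:, 1:] = np.diag(Wd) + Sigma_inv
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.solve(H + 1e-8 * np.eye(n + 1), grad)
            t = 1.0
            for _ in range(30):
                b_new, w_new = b0 + t * step[0], w + t * step[1:]
                J_new = joint(b_new, w_new)
                if J_new >= J - 1e-12:
                    break
                t /= 2
            b0, w, J_prev, J = b_new, w_new, J, J_new
            if abs(J - J_prev) < tol * (1 + abs(J)):
                break
        eta = b0 + w
        Wd = k * v * np.exp(-eta)
        H = np.zeros((n + 1, n + 1))
        H[0, 0] = Wd.sum()
        H[0, 1:] = Wd
        H[1:, 0] = Wd
        H[1:, 1:] = np.diag(Wd) + Sigma_inv
        return b0, w, H

    def neg_reml(theta):
        s2u, s2b, rho, nu = unpack(theta)
        try:
            Sigma_inv, L = sigma_inv_for(s2u, s2b, rho, nu)
        except np.linalg.LinAlgError:
            return 1e10
        b0, w, H = joint_inner(Sigma_inv, cache["b0"], cache["w"])
        cache["b0"], cache["w"] = b0, w.copy()
        eta = b0 + w
        g = const + float(np.sum(-k * eta - k * v * np.exp(-eta)))
        sign, logdetH = np.linalg.slogdet(H)
        if sign <= 0:
            return 1e10
        ll = (g - 0.5 * w @ Sigma_inv @ w - 0.5 * _logdet_from_chol(L)
              - 0.5 * logdetH + 0.5 * np.log(2 * np.pi))
        return -ll

    rng = np.random.default_rng(seed)
    best = None
    lv = max(np.var(np.log(v)) / 2, 1e-3)
    for s in range(n_starts):
        jit = np.zeros(4) if s == 0 else rng.uniform(-1.5, 1.5, size=4)
        theta0 = [np.log(lv) + jit[0], np.log(lv) + jit[1], np.log(span / 4) + 0.5 * jit[2]]
        if estimate_nu:
            theta0.append(np.log(1.0) + 0.3 * jit[3])
        bounds = [_LOGV_BOUNDS, _LOGV_BOUNDS, _LOGRHO_BOUNDS] + (
            [_LOGNU_BOUNDS] if estimate_nu else []
        )
        res = minimize(neg_reml, theta0, method="L-BFGS-B", bounds=bounds,
                       options={"ftol": 1e-9, "maxiter": 200})
        if best is None or res.fun < best.fun:
            best = res

    s2u, s2b, rho, nu = unpack(best.x)
    Sigma_inv, L = sigma_inv_for(s2u, s2b, rho, nu)
    # intercept by marginal ML at the restricted covariance estimates
    from scipy.optimize import minimize_scalar

    def neg_ll_b0(b0):
        w, H = _disp_inner(v, k, b0, Sigma_inv, cache["w"])
        eta = b0 + w
        g = float(np.sum(-k * eta - k * v * np.exp(-eta)))
        sign, logdetH = np.linalg.slogdet(H)
        if sign <= 0:
            return 1e10
        return -(g - 0.5 * w @ Sigma_inv @ w - 0.5 * logdetH)

    r = minimize_scalar(neg_ll_b0, bounds=(cache["b0"] - 6, cache["b0"] + 6),
                        method="bounded", options={"xatol": 1e-7})
    beta0 = float(r.x)
    w, _ = _disp_inner(v, k, beta0, Sigma_inv, cache["w"])
    phi = pd.Series(np.exp(beta0 + w), index=sub["site_id"].to_numpy(), name="phi_hat")
    _, _, H_ext = joint_inner(Sigma_inv, beta0, w)
    beta0_se = float(np.sqrt(np.linalg.inv(H_ext)[0, 0]))

    return DispersionModelFit(
        beta_d0=float(beta0),
        beta_d0_se=beta0_se,
        matern_d=MaternParams(nu=float(nu), rho=float(rho), sigma2=float(s2u)),
        site_var_d=float(s2b),
        loglik=float(-best.fun),
        converged=bool(best.success),
        predicted_phi=phi,
        _coords=coords,
        _w_hat=w,
    )


def predict_dispersion(fit: DispersionModelFit, sites: pd.DataFrame) -> pd.Series:
    """Residual variance phi_hat per site, response-scale plug-in.

    Sites in the fit get exp of their fitted linear predictor; unseen
    sites (e.g. single-observation sites) get the spatial BLUP of the
    latent field without a site effect, so a site far from all data tends
    to exp(beta_d0).
    """
    out = np.empty(len(sites))
    fitted = fit.predicted_phi
    coords = sites[["lon", "lat"]].to_numpy(dtype=float)
    need_blup = []
    for i, sid in enumerate(sites["site_id"]):
        if sid in fitted.index:
            out[i] = fitted.loc[sid]
        else:
            need_blup.append(i)
    if need_blup:
        m = fit.matern_d
        n = len(fit._coords)
        Sig = _re_cov(_dist_matrix(fit._coords), m.sigma2, fit.site_var_d, m.rho, m.nu)
        Sig[np.diag_indices(n)] += 1e-8
        L = sla.cholesky(Sig, lower=True)
        alpha = _chol_solve(L, fit._w_hat)
        for i in need_blup:
            d0 = np.sqrt(((fit._coords - coords[i]) ** 2).sum(axis=1))
            c0 = m.sigma2 * matern_correlation(d0, m.nu, m.rho)
            out[i] = np.exp(fit.beta_d0 + c0 @ alpha)
    return pd.Series(out, index=sites["site_id"].to_numpy(), name="phi_hat")


# ---------------------------------------------------------------------------
# model specification

@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect structure of a mean model; spatial + site REs always on."""

    fixed_effects: tuple[str, ...] = ()
    include_spatial: bool = True
    include_site: bool = True

    def __post_init__(self) -> None:
        for term in self.fixed_effects:
            if ":" in term:
                a, b = term.split(":")
                if a not in self.fixed_effects or b not in self.fixed_effects:
                    raise ValueError(
                        f"interaction {term} requires both main effects in the spec"
                    )
    def label(self) -> str:
        return " + ".join(self.fixed_effects) if self.fixed_effects else "no fixed effects"

    @classmethod
    def parse(cls, s: str) -> "ModelSpec":
        s = s.strip()
        if s.lower() in {"", "none", "no fixed effects"}:
            return cls(())
        return cls(tuple(t.strip() for t in s.split("+")))


def enumerate_model_set() -> list[ModelSpec]:
    """The twelve candidate fixed-effect structures compared per bin."""
    specs = [
        (),
        ("MAT",),
        ("MAP",),
        ("MAT", "MAP"),
        ("MAT", "MAP", "MAT:MAP"),
        ("temp.warm",),
        ("precip.warm",),
        ("precip.cold",),
        ("temp.warm", "precip.warm"),
        ("temp.warm", "precip.cold"),
        ("precip.cold", "precip.warm"),
        ("temp.warm", "precip.cold", "precip.warm"),
    ]
    return [ModelSpec(s) for s in specs]


def _design_matrix(data: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    cols = ["(Intercept)"]
    X = [np.ones(len(data))]
    for term in spec.fixed_effects:
        if ":" in term:
            a, b = term.split(":")
            X.append(data[a].to_numpy(dtype=float) * data[b].to_numpy(dtype=float))
        else:
            X.append(data[term].to_numpy(dtype=float))
        cols.append(term)
    Xm = np.column_stack(X)
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        # name the offending columns via QR pivoting
        _, R, piv = sla.qr(Xm, pivoting=True)
        diag = np.abs(np.diag(R))
        bad = [cols[piv[i]] for i in range(len(diag)) if diag[i] < 1e-10 * diag.max()]
        bad += [cols[p] for p in piv[len(diag):]]
        raise ValueError(f"rank-deficient design matrix; collinear column(s): {bad}")
    return Xm, cols


# ---------------------------------------------------------------------------
# mean model

@dataclass
class MeanModelFit:
    """Heteroscedastic Matérn LMM fit for site-mean δ15N."""

    spec: ModelSpec
    beta: pd.Series
    beta_se: pd.Series
    matern_m: MaternParams
    site_var_m: float
    residual_variances: np.ndarray     # eps variance per site, held fixed
    reml_loglik: float
    cond_loglik: float
    effective_df: float
    caic: float
    converged: bool
    n_sites: int
    # internals for prediction
    _coords: np.ndarray = dc_field(default=None, repr=False)
    _X: np.ndarray = dc_field(default=None, repr=False)
    _y: np.ndarray = dc_field(default=None, repr=False)
    _alpha: np.ndarray = dc_field(default=None, repr=False)       # Sigma^-1 r
    _Sigma_inv: np.ndarray = dc_field(default=None, repr=False)
    _XtSiX_inv: np.ndarray = dc_field(default=None, repr=False)
    _colnames: list[str] = dc_field(default=None, repr=False)
    _site_ids: np.ndarray = dc_field(default=None, repr=False)
    _cond_fitted: np.ndarray = dc_field(default=None, repr=False)


def fit_mean_model(
    aggregates: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    spec: ModelSpec = ModelSpec(()),
    phi_hat: pd.Series | np.ndarray | float = 1.0,
    fix_nu: float | None = None,
    residual_scale: str = "per_mean",
    n_starts: int = 3,
    seed: int = 0,
    force_variances: dict | None = None,
    min_sites: int = 10,
) -> MeanModelFit:
    """REML fit of the heteroscedastic spatial LMM for site means.

    ``phi_hat`` is the dispersion-model prediction per site (Series keyed
    by site_id, array aligned with ``aggregates``, or scalar).  With
    ``residual_scale="per_mean"`` the residual variance of a site mean is
    phi_hat_i / n_i; ``"raw"`` uses phi_hat_i unscaled.  ``force_variances``
    can pin ``sigma2_u`` / ``sigma2_b`` (used to recover plain GLS/OLS as a
    degenerate case).  Variance parameters are optimized by multi-start
    bounded quasi-Newton on the log scale; beta is profiled by GLS.
    """
    data = aggregates.copy()
    if covariates is not None:
        keys = [k for k in ("site_id", "bin") if k in covariates.columns and k in data.columns]
        add = [c for c in covariates.columns if c not in keys and c not in data.columns]
        data = data.merge(covariates[keys + add], on=keys, how="left")
    needed = set()
    for t in spec.fixed_effects:
        needed.update(t.split(":"))
    miss_cols = [c for c in needed if c not in data.columns]
    if miss_cols:
        raise ValueError(f"covariate column(s) missing: {miss_cols}")
    if needed:
        ok = data[sorted(needed)].notna().all(axis=1)
        data = data[ok]
    if len(data) < min_sites:
        raise ValueError(f"mean model needs >= {min_sites} sites, got {len(data)}")

    y = data["mean_d15N"].to_numpy(dtype=float)
    n = len(y)
    coords = data[["lon", "lat"]].to_numpy(dtype=float)
    n_obs = data["n_obs"].to_numpy(dtype=float)
    X, colnames = _design_matrix(data, spec)
    p = X.shape[1]

    if isinstance(phi_hat, pd.Series):
        phi = phi_hat.reindex(data["site_id"]).to_numpy(dtype=float)
        if np.any(~np.isfinite(phi)):
            raise ValueError("phi_hat missing for some sites")
    else:
        phi = np.broadcast_to(np.asarray(phi_hat, dtype=float), (n,)).copy()
    D = phi / n_obs if residual_scale == "per_mean" else phi.copy()
    D = np.maximum(D, 0.0)

    dist = _dist_matrix(coords)
    span = max(dist.max(), 1e-3)
    force_variances = force_variances or {}
    estimate_nu = fix_nu is None and "nu" not in force_variances

    free: list[str] = []
    if "sigma2_u" not in force_variances:
        free.append("sigma2_u")
    if "sigma2_b" not in force_variances:
        free.append("sigma2_b")
    spatial_on = "sigma2_u" not in force_variances or force_variances["sigma2_u"] > 0
    if spatial_on and "rho" not in force_variances:
        free.append("rho")
    if spatial_on and estimate_nu:
        free.append("nu")

    def unpack(theta):
        vals = dict(zip(free, theta))
        s2u = np.exp(vals["sigma2_u"]) if "sigma2_u" in vals else force_variances["sigma2_u"]
        s2b = np.exp(vals["sigma2_b"]) if "sigma2_b" in vals else force_variances["sigma2_b"]
        rho = np.exp(vals["rho"]) if "rho" in vals else force_variances.get("rho", span / 4)
        if "nu" in vals:
            nu = np.exp(vals["nu"])
        else:
            nu = fix_nu if fix_nu is not None else force_variances.get("nu", 1.0)
        return s2u, s2b, rho, nu

    def reml_ll(s2u, s2b, rho, nu):
        Sigma = _re_cov(dist, s2u, s2b, rho, nu)
        Sigma[np.diag_indices(n)] += D + 1e-10
        try:
            L = sla.cholesky(Sigma, lower=True)
        except np.linalg.LinAlgError:
            return None
        Si_X = _chol_solve(L, X)
        Si_y = _chol_solve(L, y)
        XtSiX = X.T @ Si_X
        try:
            Lx = sla.cholesky(XtSiX, lower=True)
        except np.linalg.LinAlgError:
            return None
        beta = sla.cho_solve((Lx, True), X.T @ Si_y)
        r = y - X @ beta
        Si_r = _chol_solve(L, r)
        ll = -0.5 * (
            _logdet_from_chol(L)
            + _logdet_from_chol(Lx)
            + r @ Si_r
            + (n - p) * np.log(2 * np.pi)
        )
        return ll, L, beta, r, Si_r, XtSiX, Lx

    def neg_ll(theta):
        out = reml_ll(*unpack(theta))
        return 1e10 if out is None else -out[0]

    if free:
        rng = np.random.default_rng(seed)
        vy = max(np.var(y), 1e-6)
        best = None
        for s in range(n_starts):
            jit = rng.uniform(-1.0, 1.0, size=len(free))
            theta0 = []
            bounds = []
            for f, j in zip(free, jit):
                if f in ("sigma2_u", "sigma2_b"):
                    theta0.append(np.log(vy / 2) + j)
                    bounds.append(_LOGV_BOUNDS)
                elif f == "rho":
                    theta0.append(np.log(span / 4) + 0.5 * j)
                    bounds.append(_LOGRHO_BOUNDS)
                else:
                    theta0.append(0.3 * j)
                    bounds.append(_LOGNU_BOUNDS)
            res = minimize(neg_ll, theta0, method="L-BFGS-B", bounds=bounds,
                           options={"ftol": 1e-9, "maxiter": 300})
            if best is None or res.fun < best.fun:
                best = res
        theta_hat = best.x
        converged = bool(best.success and best.fun < 1e9)
    else:
        theta_hat = np.array([])
        converged = True

    s2u, s2b, rho, nu = unpack(theta_hat)
    out = reml_ll(s2u, s2b, rho, nu)
    if out is None:
        raise RuntimeError("covariance matrix not positive definite at the optimum")
    ll, L, beta, r, Si_r, XtSiX, Lx = out

    Sigma_inv = _chol_solve(L, np.eye(n))
    XtSiX_inv = sla.cho_solve((Lx, True), np.eye(p))
    beta_se = np.sqrt(np.diag(XtSiX_inv))

    # conditional fit and cAIC
    re_cov = _re_cov(dist, s2u, s2b, rho, nu)
    cond_fitted = X @ beta + re_cov @ Si_r
    D_safe = np.maximum(D, 1e-10)
    cond_ll = float(
        -0.5 * np.sum((y - cond_fitted) ** 2 / D_safe + np.log(2 * np.pi * D_safe))
    )
    A = X @ (XtSiX_inv @ (X.T @ Sigma_inv))
    M = A + re_cov @ Sigma_inv @ (np.eye(n) - A)
    n_cov_params = len(free)
    eff_df = float(np.trace(M)) + n_cov_params
    caic_val = -2.0 * cond_ll + 2.0 * eff_df

    return MeanModelFit(
        spec=spec,
        beta=pd.Series(beta, index=colnames),
        beta_se=pd.Series(beta_se, index=colnames),
        matern_m=MaternParams(nu=float(nu), rho=float(rho), sigma2=float(s2u)),
        site_var_m=float(s2b),
        residual_variances=D,
        reml_loglik=float(ll),
        cond_loglik=cond_ll,
        effective_df=eff_df,
        caic=float(caic_val),
        converged=converged,
        n_sites=n,
        _coords=coords,
        _X=X,
        _y=y,
        _alpha=Si_r,
        _Sigma_inv=Sigma_inv,
        _XtSiX_inv=XtSiX_inv,
        _colnames=colnames,
        _site_ids=data["site_id"].to_numpy() if "site_id" in data.columns else None,
        _cond_fitted=cond_fitted,
    )


def caic(fit: MeanModelFit) -> float:
    """Conditional AIC: -2 * conditional log-likelihood + 2 * effective df."""
    return float(-2.0 * fit.cond_loglik + 2.0 * fit.effective_df)


def select_best_model(fits: list[MeanModelFit]) -> pd.DataFrame:
    """Rank converged fits by ascending cAIC; ties by fewer fixed effects."""
    conv = [f for f in fits if f.converged]
    if not conv:
        raise ValueError("no converged fits to rank")
    rows = [
        {
            "model": f.spec.label(),
            "n_fixed": len(f.spec.fixed_effects),
            "caic": f.caic,
            "converged": f.converged,
            "fit": f,
        }
        for f in conv
    ]
    tab = pd.DataFrame(rows).sort_values(["caic", "n_fixed"], kind="mergesort").reset_index(drop=True)
    tab["delta_caic"] = tab["caic"] - tab["caic"].iloc[0]
    skipped = [f.spec.label() for f in fits if not f.converged]
    tab.attrs["non_converged"] = skipped
    return tab


# ---------------------------------------------------------------------------
# prediction

def predict_points(
    fit: MeanModelFit,
    points: np.ndarray,
    x0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Universal-kriging prediction and variance at arbitrary points.

    prediction = x0' beta + c0' Sigma^-1 (y - X beta), with c0 the spatial
    covariance between the point and the data sites; variance = sigma2_u +
    sigma2_b - c0' Sigma^-1 c0 + g0' (X' Sigma^-1 X)^-1 g0 with
    g0 = x0 - X' Sigma^-1 c0.  Fixed-effect uncertainty is included;
    residual sampling variance is not.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    m = fit.matern_m
    if x0 is None:
        if len(fit._colnames) > 1:
            raise ValueError("fit has covariates: supply x0 design rows")
        x0 = np.ones((len(points), 1))
    x0 = np.atleast_2d(x0)
    diff = points[:, None, :] - fit._coords[None, :, :]
    d0 = np.sqrt((diff**2).sum(axis=-1))
    C0 = m.sigma2 * matern_correlation(d0, m.nu, m.rho) if m.sigma2 > 0 else np.zeros_like(d0)
    # a prediction point coinciding with a data site shares its site effect
    at_site = d0 < 1e-9
    if fit.site_var_m > 0 and at_site.any():
        C0 = C0 + fit.site_var_m * at_site

    pred = x0 @ fit.beta.to_numpy() + C0 @ fit._alpha
    SiC0 = fit._Sigma_inv @ C0.T                       # (n, npts)
    g0 = x0.T - fit._X.T @ SiC0                        # (p, npts)
    var = (
        m.sigma2 + fit.site_var_m
        - np.einsum("ij,ji->i", C0, SiC0)
        + np.einsum("pi,pq,qi->i", g0, fit._XtSiX_inv, g0)
    )
    return pred, np.maximum(var, 0.0)


@dataclass
class IsoscapeRaster:
    """Gridded prediction and prediction-variance surfaces for one bin/model."""

    bin: str | None
    spec: ModelSpec
    lon: np.ndarray
    lat: np.ndarray
    prediction: np.ndarray
    prediction_variance: np.ndarray
    mask_applied: bool = False
    n_masked_missing_covariate: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        LO, LA = np.meshgrid(self.lon, self.lat)
        return pd.DataFrame(
            {
                "lon": LO.ravel(),
                "lat": LA.ravel(),
                "prediction": self.prediction.ravel(),
                "prediction_variance": self.prediction_variance.ravel(),
            }
        )


def predict_isoscape(
    fit: MeanModelFit,
    rasters: dict | None = None,
    time_step: int | str | None = None,
    lon_window: tuple[float, float] = (-10.0, 30.0),
    lat_window: tuple[float, float] = (35.0, 60.0),
    resolution: float = 0.5,
    mask: ClimateRaster | None = None,
    bin_name: str | None = None,
) -> IsoscapeRaster:
    """Predict the isoscape over a regular grid.

    For specs with covariates, ``rasters`` (keyed (variable, time_step))
    and ``time_step`` supply the fixed-effect values at each cell; cells
    with a missing covariate are masked and tallied.  An optional 0/1
    ``mask`` raster blanks cells where it is 0 or missing.
    """
    if not fit.converged:
        raise ValueError("cannot predict from a non-converged fit")
    lon = np.arange(lon_window[0] + resolution / 2, lon_window[1], resolution)
    lat = np.arange(lat_window[0] + resolution / 2, lat_window[1], resolution)
    LO, LA = np.meshgrid(lon, lat)
    pts = np.column_stack([LO.ravel(), LA.ravel()])
    ncell = len(pts)

    needed = sorted({v for t in fit.spec.fixed_effects for v in t.split(":")})
    x0 = np.ones((ncell, len(fit._colnames)))
    missing = np.zeros(ncell, dtype=bool)
    if needed:
        if rasters is None or time_step is None:
            raise ValueError("spec has covariates: supply rasters and time_step")
        covcells = {}
        for vname in needed:
            key = (vname, "modern" if vname == "elevation" else time_step)
            if key not in rasters:
                raise ValueError(f"missing raster for {key}")
            ras = rasters[key]
            vals = np.array([
                sample_raster(ras, p[0], p[1], "bilinear") for p in pts
            ])
            covcells[vname] = vals
            missing |= ~np.isfinite(vals)
        for j, term in enumerate(fit._colnames):
            if term == "(Intercept)":
                continue
            if ":" in term:
                a, b = term.split(":")
                x0[:, j] = covcells[a] * covcells[b]
            else:
                x0[:, j] = covcells[term]
        x0[missing] = 0.0   # placeholder; masked below

    pred, var = predict_points(fit, pts, x0)
    pred[missing] = np.nan
    var[missing] = np.nan

    mask_applied = False
    if mask is not None:
        mask_applied = True
        mv = np.array([sample_raster(mask, p[0], p[1], "nearest") for p in pts])
        blank = ~(np.isfinite(mv) & (mv > 0))
        pred[blank] = np.nan
        var[blank] = np.nan

    return IsoscapeRaster(
        bin=bin_name,
        spec=fit.spec,
        lon=lon,
        lat=lat,
        prediction=pred.reshape(len(lat), len(lon)),
        prediction_variance=var.reshape(len(lat), len(lon)),
        mask_applied=mask_applied,
        n_masked_missing_covariate=int(missing.sum()),
    )


def predicted_vs_observed(fit: MeanModelFit, aggregates: pd.DataFrame | None = None) -> dict:
    """Leave-location-in diagnostics at the data sites.

    Returns the per-site table (observed, predicted, residual) plus the
    slope/intercept of observed ~ predicted and the RMSE.  BLUP shrinkage
    makes the regression slope of observed on predicted tend to exceed 1
    on noisy data (high values under-predicted, low values over-predicted).
    """
    obs = fit._y
    pred = fit._cond_fitted
    resid = obs - pred
    slope, intercept = np.polyfit(pred, obs, 1) if np.ptp(pred) > 0 else (np.nan, np.nan)
    table = pd.DataFrame(
        {
            "site_id": fit._site_ids if fit._site_ids is not None else np.arange(len(obs)),
            "observed": obs,
            "predicted": pred,
            "residual": resid,
        }
    )
    return {
        "table": table,
        "slope": float(slope),
        "intercept": float(intercept),
        "rmse": float(np.sqrt(np.mean(resid**2))),
    }
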