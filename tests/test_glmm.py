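"""Two-step mixed model: aggregation, dispersion fit, REML mean model,
cAIC, and kriging prediction."""

import numpy as np
import pandas as pd
import pytest

from paleoscape import (
    ModelSpec,
    aggregate_by_site,
    caic,
    enumerate_model_set,
    fit_dispersion_model,
    fit_mean_model,
    predict_dispersion,
    predict_isoscape,
    predict_points,
    predicted_vs_observed,
    select_best_model,
)
from paleoscape.matern import matern_correlation


class TestAggregate:
    def test_hand_arithmetic(self):
        df = pd.DataFrame(
            {
                "site_id": ["s", "s"],
                "bin": ["LGM", "LGM"],
                "longitude": [1.0, 1.0],
                "latitude": [2.0, 2.0],
                "d15N": [3.0, 5.0],
            }
        )
        agg = aggregate_by_site(df, "LGM")
        row = agg.iloc[0]
        assert (row["mean_d15N"], row["var_d15N"], row["n_obs"]) == (4.0, 2.0, 2)

    def test_single_observation_site_has_missing_variance(self):
        df = pd.DataFrame(
            {"site_id": ["s"], "bin": ["LGM"], "longitude": [1.0], "latitude": [2.0],
             "d15N": [3.0]}
        )
        agg = aggregate_by_site(df, "LGM")
        assert agg["n_obs"].iloc[0] == 1 and np.isnan(agg["var_d15N"].iloc[0])

    def test_taxon_filter(self):
        df = pd.DataFrame(
            {
                "site_id": ["s", "s", "t"],
                "bin": "LGM",
                "longitude": 1.0,
                "latitude": 2.0,
                "taxon": ["Equus sp.", "Rangifer tarandus", "Equus sp."],
                "d15N": [3.0, 9.0, 5.0],
            }
        )
        agg = aggregate_by_site(df, "LGM", taxon_filter="Equus sp.")
        assert agg["n_obs"].sum() == 2

    def test_empty_errors(self):
        df = pd.DataFrame({"site_id": [], "bin": [], "longitude": [], "latitude": [],
                           "d15N": []})
        with pytest.raises(ValueError):
            aggregate_by_site(df, "LGM")


class TestModelSpecs:
    def test_twelve_candidates(self):
        specs = enumerate_model_set()
        assert len(specs) == 12
        labels = [s.label() for s in specs]
        assert "MAT + MAP + MAT:MAP" in labels
        assert "no fixed effects" in labels

    def test_interaction_requires_main_effects(self):
        with pytest.raises(ValueError):
            ModelSpec(("MAT", "MAT:MAP"))

    def test_parse_spec_string(self):
        s = ModelSpec.parse("MAT+MAP+MAT:MAP")
        assert s.fixed_effects == ("MAT", "MAP", "MAT:MAP")
        assert ModelSpec.parse("none").fixed_effects == ()


class TestMeanModel:
    def test_degenerate_gls_equals_ols(self, small_aggregates):
        agg = small_aggregates.copy()
        rng = np.random.default_rng(1)
        agg["x"] = rng.normal(0, 1, len(agg))
        fit = fit_mean_model(
            agg, spec=ModelSpec(("x",)), phi_hat=1.0, residual_scale="raw",
            force_variances={"sigma2_u": 0.0, "sigma2_b": 0.0}, min_sites=5,
        )
        X = np.column_stack([np.ones(len(agg)), agg["x"]])
        beta_ols = np.linalg.lstsq(X, agg["mean_d15N"], rcond=None)[0]
        np.testing.assert_allclose(fit.beta.to_numpy(), beta_ols, atol=1e-10)

    def test_rank_deficient_design_names_column(self, small_aggregates):
        agg = small_aggregates.copy()
        agg["x"] = 1.0            # constant alongside the intercept
        with pytest.raises(ValueError, match="x"):
            fit_mean_model(agg, spec=ModelSpec(("x",)), phi_hat=1.0, min_sites=5)

    def test_too_few_sites(self, small_aggregates):
        with pytest.raises(ValueError, match="sites"):
            fit_mean_model(small_aggregates.head(4), phi_hat=1.0, min_sites=10)

    def test_missing_covariate_column(self, small_aggregates):
        with pytest.raises(ValueError, match="MAT"):
            fit_mean_model(small_aggregates, spec=ModelSpec(("MAT",)), phi_hat=1.0,
                           min_sites=5)


@pytest.fixture()
def kriging_fit(small_aggregates):
    agg = small_aggregates.head(8)
    params = dict(sigma2_u=1.5, sigma2_b=0.0, rho=3.0, nu=1.0)
    fit = fit_mean_model(agg, phi_hat=1e-8, residual_scale="raw",
                         force_variances=params, min_sites=5)
    return fit, agg, params


class TestKriging:
    def test_matches_dense_gaussian_conditioning(self, kriging_fit):
        """Oracle: joint-MVN conditional mean/variance with GLS mean."""
        fit, agg, p = kriging_fit
        coords = agg[["lon", "lat"]].to_numpy()
        y = agg["mean_d15N"].to_numpy()
        n = len(y)
        rng = np.random.default_rng(9)
        probes = rng.uniform(0, 10, (5, 2))

        def cov(a, b):
            d = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1))
            return p["sigma2_u"] * matern_correlation(d, p["nu"], p["rho"])

        K = cov(coords, coords) + (1e-8 + 1e-10) * np.eye(n)
        Ki = np.linalg.inv(K)
        ones = np.ones((n, 1))
        denom = (ones.T @ Ki @ ones).item()
        bgls = (ones.T @ Ki @ y).item() / denom
        k0 = cov(probes, coords)
        m0 = bgls + k0 @ Ki @ (y - bgls)
        v0 = (p["sigma2_u"] - np.einsum("ij,jk,ik->i", k0, Ki, k0)
              + (1 - (ones.T @ Ki @ k0.T).ravel()) ** 2 / denom)

        pred, var = predict_points(fit, probes)
        np.testing.assert_allclose(pred, m0, atol=1e-8)
        np.testing.assert_allclose(var, v0, atol=1e-8)

    def test_zero_nugget_interpolates_site_means(self, kriging_fit):
        fit, agg, _ = kriging_fit
        coords = agg[["lon", "lat"]].to_numpy()
        pred, var = predict_points(fit, coords)
        np.testing.assert_allclose(pred, agg["mean_d15N"], atol=1e-6)
        assert np.all(var >= 0) and np.all(var < 1e-6)

    def test_decorrelation_limit(self, kriging_fit):
        fit, agg, p = kriging_fit
        pred, var = predict_points(fit, np.array([[500.0, 500.0]]))
        assert pred[0] == pytest.approx(fit.beta.iloc[0], abs=1e-8)
        assert var[0] == pytest.approx(
            p["sigma2_u"] + p["sigma2_b"] + fit.beta_se.iloc[0] ** 2, abs=1e-8
        )

    def test_variance_nonnegative_on_grid(self, kriging_fit):
        fit, _, _ = kriging_fit
        surf = predict_isoscape(fit, lon_window=(0, 10), lat_window=(0, 10),
                                resolution=1.0)
        assert np.all(surf.prediction_variance >= 0)
        assert np.all(np.isfinite(surf.prediction))


class TestCaic:
    def test_degenerate_limit_equals_weighted_aic(self, small_aggregates):
        agg = small_aggregates.copy()
        rng = np.random.default_rng(2)
        agg["x"] = rng.normal(0, 1, len(agg))
        fit = fit_mean_model(
            agg, spec=ModelSpec(("x",)), phi_hat=1.0, residual_scale="raw",
            force_variances={"sigma2_u": 0.0, "sigma2_b": 0.0}, min_sites=5,
        )
        n, p = len(agg), 2
        X = np.column_stack([np.ones(n), agg["x"]])
        beta = np.linalg.lstsq(X, agg["mean_d15N"], rcond=None)[0]
        r = agg["mean_d15N"].to_numpy() - X @ beta
        ll = -0.5 * np.sum(r**2 + np.log(2 * np.pi))
        assert fit.effective_df == pytest.approx(p, abs=1e-6)
        assert caic(fit) == pytest.approx(-2 * ll + 2 * p, abs=1e-6)

    def test_effective_df_grows_with_spatial_variance(self, small_aggregates):
        effs = []
        for s2u in (0.01, 0.5, 5.0, 50.0):
            fit = fit_mean_model(
                small_aggregates, phi_hat=1.0, residual_scale="raw",
                force_variances={"sigma2_u": s2u, "sigma2_b": 0.0, "rho": 3.0, "nu": 1.0},
                min_sites=5,
            )
            effs.append(fit.effective_df)
        assert np.all(np.diff(effs) > 0)

    def test_caic_function_matches_field(self, small_aggregates):
        fit = fit_mean_model(small_aggregates, phi_hat=1.0, fix_nu=0.5,
                             n_starts=1, min_sites=5)
        assert caic(fit) == pytest.approx(fit.caic)


class TestSelection:
    def test_ranking_and_deltas(self, small_aggregates):
        fits = []
        for s2u, spec in [(0.5, ModelSpec(())), (2.0, ModelSpec(())), (8.0, ModelSpec(()))]:
            fits.append(
                fit_mean_model(small_aggregates, phi_hat=1.0, residual_scale="raw",
                               force_variances={"sigma2_u": s2u, "sigma2_b": 0.0,
                                                "rho": 3.0, "nu": 1.0}, min_sites=5)
            )
        tab = select_best_model(fits)
        assert list(tab["caic"]) == sorted(tab["caic"])
        assert tab["delta_caic"].iloc[0] == 0.0

    def test_no_converged_fits_errors(self, small_aggregates):
        fit = fit_mean_model(small_aggregates, phi_hat=1.0, fix_nu=0.5,
                             n_starts=1, min_sites=5)
        fit.converged = False
        with pytest.raises(ValueError):
            select_best_model([fit])


class TestDispersion:
    def test_constant_variances_recover_intercept_with_no_field(self):
        rng = np.random.default_rng(9)
        n = 40
        agg = pd.DataFrame(
            {"site_id": [f"D{i}" for i in range(n)],
             "lon": rng.uniform(0, 10, n), "lat": rng.uniform(0, 10, n),
             "n_obs": np.full(n, 200), "mean_d15N": 0.0, "var_d15N": 2.0}
        )
        fit = fit_dispersion_model(agg, seed=1, fix_nu=0.5, n_starts=2)
        assert fit.beta_d0 == pytest.approx(np.log(2.0), abs=1e-3)
        assert fit.matern_d.sigma2 < 1e-4 and fit.site_var_d < 1e-4
        np.testing.assert_allclose(fit.predicted_phi, 2.0, atol=1e-2)

    def test_too_few_multi_observation_sites(self, small_aggregates):
        agg = small_aggregates.copy()
        agg["n_obs"] = 1
        agg["var_d15N"] = np.nan
        with pytest.raises(ValueError, match="5 sites"):
            fit_dispersion_model(agg)

    def test_predictions_positive_and_far_site_returns_intercept(self, small_aggregates):
        agg = small_aggregates.copy()
        agg["n_obs"] = np.maximum(agg["n_obs"], 2)
        fit = fit_dispersion_model(agg, seed=0, fix_nu=0.5, n_starts=1)
        phi = predict_dispersion(fit, agg)
        assert (phi > 0).all()
        far = pd.DataFrame({"site_id": ["far"], "lon": [900.0], "lat": [900.0]})
        phi_far = predict_dispersion(fit, far)
        assert phi_far.iloc[0] == pytest.approx(np.exp(fit.beta_d0), rel=1e-6)


class TestDiagnostics:
    def test_perfect_fit_has_unit_slope_and_zero_rmse(self, small_aggregates):
        fit = fit_mean_model(small_aggregates, phi_hat=1e-10, residual_scale="raw",
                             force_variances={"sigma2_u": 2.0, "sigma2_b": 0.0,
                                              "rho": 3.0, "nu": 1.0}, min_sites=5)
        diag = predicted_vs_observed(fit)
        assert diag["slope"] == pytest.approx(1.0, abs=1e-4)
        assert diag["rmse"] < 1e-4
        assert len(diag["table"]) == fit.n_sites
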