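"""Spatial weights, Local/Global Moran's I, FDR and outlier classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paleoscape import (
    build_inverse_distance_weights,
    classify_and_filter,
    fdr_adjust,
    global_moran,
    jitter_coincident,
    local_moran,
)
from paleoscape.moran import CLUSTER_LABELS


class TestJitter:
    def test_distinct_points_untouched(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 0.5]])
        np.testing.assert_array_equal(jitter_coincident(pts, seed=3), pts)

    def test_coincident_group_displaced_within_box(self):
        pts = np.tile([[10.0, 45.0]], (5, 1))
        out = jitter_coincident(pts, magnitude=0.1, seed=1)
        np.testing.assert_array_equal(out[0], pts[0])       # first member kept
        moved = out[1:]
        d = np.sqrt(((moved - pts[0]) ** 2).sum(axis=1))
        assert np.all(d > 0) and np.all(d <= 0.1 * np.sqrt(2) / 2 + 1e-12)
        assert len(np.unique(np.round(moved, 12), axis=0)) == 4

    def test_deterministic_given_seed(self):
        pts = np.tile([[0.0, 0.0]], (4, 1))
        a = jitter_coincident(pts, seed=7)
        b = jitter_coincident(pts, seed=7)
        c = jitter_coincident(pts, seed=8)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)


class TestWeights:
    def test_hand_inverse_distances(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        W = build_inverse_distance_weights(pts, row_standardize=False)
        np.testing.assert_allclose(
            W.weights, [[0, 1, 0.5], [1, 0, 1], [0.5, 1, 0]]
        )

    def test_row_standardization(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        W = build_inverse_distance_weights(pts)
        np.testing.assert_allclose(W.weights[0], [0, 2 / 3, 1 / 3])
        np.testing.assert_allclose(W.weights.sum(axis=1), 1.0, atol=1e-10)

    def test_coincident_points_error_mentions_jitter(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="jitter"):
            build_inverse_distance_weights(pts)


def _direct_local_moran(values, w):
    """Independent evaluation of Ii straight from the definition."""
    x = np.asarray(values, float)
    z = x - x.mean()
    m2 = (z**2).sum() / len(x)
    return (z / m2) * (w @ z)


def _direct_global_moran(values, w):
    x = np.asarray(values, float)
    z = x - x.mean()
    return (len(x) / w.sum()) * (z @ w @ z) / (z**2).sum()


class TestLocalMoran:
    def test_constant_values_give_zero_index(self):
        pts = np.random.default_rng(0).uniform(0, 5, (6, 2))
        W = build_inverse_distance_weights(pts)
        res = local_moran(np.full(6, 3.3), W, n_perm=49, seed=0)
        np.testing.assert_array_equal(res.Ii, 0.0)
        np.testing.assert_array_equal(res.p_raw, 1.0)

    def test_extreme_value_among_similar_neighbours_is_negative(self):
        pts = np.array([[0, 0], [0.5, 0], [0, 0.5], [0.5, 0.5], [0.25, 0.25], [10, 10]])
        vals = np.array([5.0, 5.1, 4.9, 5.0, -3.0, 5.0])   # index 4 dissimilar to its tight cluster
        W = build_inverse_distance_weights(pts)
        res = local_moran(vals, W, n_perm=99, seed=1)
        assert res.Ii[4] < 0

    def test_matches_direct_formula_and_additivity(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            n = int(rng.integers(5, 13))
            pts = rng.uniform(0, 10, (n, 2))
            vals = rng.normal(0, 1, n)
            W = build_inverse_distance_weights(pts)
            res = local_moran(vals, W, n_perm=19, seed=0)
            np.testing.assert_allclose(res.Ii, _direct_local_moran(vals, W.weights), atol=1e-9)
            g = global_moran(vals, W)
            assert abs(res.Ii.sum() - n * g.I) < 1e-9

    def test_pvalues_in_range_and_reproducible(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 10, (10, 2))
        vals = rng.normal(0, 1, 10)
        W = build_inverse_distance_weights(pts)
        a = local_moran(vals, W, n_perm=99, seed=5)
        b = local_moran(vals, W, n_perm=99, seed=5)
        np.testing.assert_array_equal(a.p_raw, b.p_raw)
        assert np.all(a.p_raw >= 1 / 100) and np.all(a.p_raw <= 1.0)
        assert np.all(a.p_fdr >= a.p_raw - 1e-15)

    def test_requires_four_points_and_standardized_weights(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        W = build_inverse_distance_weights(pts)
        with pytest.raises(ValueError):
            local_moran([1.0, 2.0, 3.0], W)
        pts4 = np.vstack([pts, [3.0, 0.0]])
        W_raw = build_inverse_distance_weights(pts4, row_standardize=False)
        with pytest.raises(ValueError, match="row-standardized"):
            local_moran([1.0, 2.0, 3.0, 4.0], W_raw)


class TestGlobalMoran:
    def test_checkerboard_is_negative(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
        vals = np.array([1.0, -1.0, -1.0, 1.0])            # interleaved highs/lows
        W = build_inverse_distance_weights(pts)
        assert global_moran(vals, W).I < 0

    def test_expected_value_is_minus_one_over_n_minus_one(self):
        rng = np.random.default_rng(4)
        n = 9
        pts = rng.uniform(0, 10, (n, 2))
        vals = rng.normal(0, 1, n)
        W = build_inverse_distance_weights(pts)
        g = global_moran(vals, W)
        assert g.expected == pytest.approx(-1 / (n - 1))
        # permutation mean of I approaches the analytic expectation
        sims = [
            global_moran(rng.permutation(vals), W).I for _ in range(300)
        ]
        assert abs(np.mean(sims) - g.expected) < 0.02

    def test_small_n_rejected_and_constant_missing(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError):
            global_moran([1.0, 2.0], build_inverse_distance_weights(pts))
        pts = np.random.default_rng(0).uniform(0, 5, (6, 2))
        g = global_moran(np.full(6, 2.0), build_inverse_distance_weights(pts))
        assert np.isnan(g.I)


class TestFdr:
    def test_hand_computed_example(self):
        got = fdr_adjust([0.002, 0.01, 0.03, 0.04])
        np.testing.assert_allclose(got, [0.008, 0.02, 0.04, 0.04])

    def test_degenerate_inputs(self):
        np.testing.assert_array_equal(fdr_adjust([1.0, 1.0, 1.0]), 1.0)
        np.testing.assert_array_equal(fdr_adjust([0.3]), [0.3])

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.1, 1.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_adjusted_at_least_raw_and_order_preserving(self, ps):
        p = np.array(ps)
        q = fdr_adjust(p)
        assert np.all(q >= p - 1e-12) and np.all(q <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestClassify:
    def test_no_significant_points_keeps_everything(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 10, (8, 2))
        vals = rng.normal(0, 1, 8)
        W = build_inverse_distance_weights(pts)
        res = local_moran(vals, W, n_perm=99, seed=0)
        res.p_fdr = np.ones(8)
        labels, keep = classify_and_filter(res, vals)
        assert set(labels) == {"NOT_SIGNIFICANT"} and len(keep) == 8

    def test_labels_from_controlled_vocabulary(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 4, (12, 2))
        vals = np.concatenate([rng.normal(8, 0.2, 6), rng.normal(0, 0.2, 6)])
        W = build_inverse_distance_weights(pts)
        res = local_moran(vals, W, n_perm=199, seed=2)
        labels, _ = classify_and_filter(res, vals)
        assert set(labels) <= set(CLUSTER_LABELS)

    def test_planted_low_value_in_high_region_removed(self):
        from paleoscape import simulate_matern_field
        from paleoscape.matern import MaternParams

        rng = np.random.default_rng(77)
        pts = rng.uniform(0, 20, (60, 2))
        field = 2 + 0.3 * pts[:, 1] + simulate_matern_field(
            pts, MaternParams(nu=1.5, rho=8.0, sigma2=0.5), seed=77
        )
        vals = field + rng.normal(0, 0.3, 60)
        k = int(np.argmax(pts[:, 1]))
        vals[k] = field.min() - 2.0
        W = build_inverse_distance_weights(pts)
        res = local_moran(vals, W, n_perm=999, seed=3)
        labels, keep = classify_and_filter(res, vals)
        assert labels[k] == "LOW_HIGH_OUTLIER" and k not in keep
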