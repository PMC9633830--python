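import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metalscreen import (
    DataError,
    SpatialWeights,
    classify_local,
    knn_weights,
    lee_global,
    lee_local,
    lee_mc,
    pairwise_haversine,
)
from conftest import brute_force_lee


class TestKnnWeights:
    def test_collinear_middle_point_neighbours(self):
        pts = np.array([[16.50 + 0.01 * i, -5.40] for i in range(5)])
        W = knn_weights(pts, k=2)
        assert sorted(W.neighbors[2]) == [1, 3]

    def test_row_standardized_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.uniform(16, 17, 30), rng.uniform(-6, -5, 30)])
        W = knn_weights(pts, k=4)
        assert np.allclose(W.row_sums(), 1.0)

    def test_matches_brute_force_all_pairs_sort(self):
        rng = np.random.default_rng(42)
        pts = np.column_stack([rng.uniform(16, 17, 50), rng.uniform(-6, -5, 50)])
        W = knn_weights(pts, k=4)
        D = pairwise_haversine(pts)
        for i in range(50):
            d = [(D[i, j], j) for j in range(50) if j != i]
            expected = [j for _, j in sorted(d)[:4]]
            assert W.neighbors[i].tolist() == expected

    def test_duplicate_coordinates_tie_break_by_index(self):
        pts = np.array([[16.6, -5.4], [16.6, -5.4], [16.6, -5.4], [16.7, -5.4]])
        W = knn_weights(pts, k=2)
        # ties at distance 0 resolve to the lowest record index
        assert W.neighbors[0].tolist() == [1, 2]
        assert W.neighbors[3].tolist() == [0, 1]

    def test_too_few_observations_rejected(self):
        with pytest.raises(DataError):
            knn_weights(np.array([[0.0, 0.0], [1.0, 1.0]]), k=4)

    def test_gal_round_trip(self):
        rng = np.random.default_rng(3)
        pts = np.column_stack([rng.uniform(16, 17, 12), rng.uniform(-6, -5, 12)])
        W = knn_weights(pts, k=3)
        buf = io.StringIO()
        W.to_gal(buf)
        buf.seek(0)
        W2 = SpatialWeights.from_gal(buf)
        assert np.array_equal(W.neighbors, W2.neighbors)
        assert np.allclose(W.weights, W2.weights)


def _paired_identity_weights(n_pairs):
    """Sites in coincident pairs with k=1: each point's neighbour is its
    duplicate, so the spatial lag of any pair-constant variable is itself."""
    rng = np.random.default_rng(10)
    base = np.column_stack(
        [rng.uniform(16, 17, n_pairs), rng.uniform(-6, -5, n_pairs)]
    )
    coords = np.repeat(base, 2, axis=0)
    vals = np.repeat(rng.standard_normal(n_pairs), 2)
    return coords, vals


class TestLeeGlobal:
    def test_reduces_to_pearson_r_on_identity_lag_fixture(self):
        coords, x = _paired_identity_weights(12)
        W = knn_weights(coords, k=1)
        assert lee_global(x, x, W) == pytest.approx(1.0, abs=1e-12)

    def test_matches_loop_oracle_on_fixture(self, six_point_fixture):
        coords, x, y = six_point_fixture
        W = knn_weights(coords, k=2)
        L_oracle, local_oracle = brute_force_lee(x, y, W)
        assert lee_global(x, y, W) == pytest.approx(L_oracle, abs=1e-12)
        assert lee_local(x, y, W) == pytest.approx(local_oracle, abs=1e-12)

    def test_mean_under_iid_null_is_near_zero(self, null_weights_100):
        rng = np.random.default_rng(21)
        W = null_weights_100
        vals = [
            lee_global(rng.standard_normal(100), rng.standard_normal(100), W)
            for _ in range(200)
        ]
        assert abs(np.mean(vals)) < 0.02

    def test_symmetry_in_x_and_y(self, six_point_fixture):
        coords, x, y = six_point_fixture
        W = knn_weights(coords, k=2)
        assert lee_global(x, y, W) == pytest.approx(lee_global(y, x, W), rel=1e-14)

    def test_affine_invariance_and_sign_flip(self, six_point_fixture):
        coords, x, y = six_point_fixture
        W = knn_weights(coords, k=2)
        L = lee_global(x, y, W)
        assert lee_global(3.2 * x + 5, y, W) == pytest.approx(L, rel=1e-12)
        assert lee_global(-2.0 * x + 1, y, W) == pytest.approx(-L, rel=1e-12)

    def test_zero_variance_rejected(self, six_point_fixture):
        coords, x, _ = six_point_fixture
        W = knn_weights(coords, k=2)
        with pytest.raises(DataError):
            lee_global(x, np.ones(6), W)

    def test_incomplete_input_rejected(self, six_point_fixture):
        coords, x, y = six_point_fixture
        W = knn_weights(coords, k=2)
        y = y.copy()
        y[0] = np.nan
        with pytest.raises(DataError):
            lee_global(x, y, W)


class TestLeeLocal:
    def test_mean_local_equals_global(self, six_point_fixture):
        coords, x, y = six_point_fixture
        W = knn_weights(coords, k=2)
        assert np.mean(lee_local(x, y, W)) == pytest.approx(lee_global(x, y, W), abs=1e-10)

    def test_zero_centered_lag_gives_zero_local(self):
        coords, _ = _paired_identity_weights(6)
        W = knn_weights(coords, k=1)
        # neighbour values mirror own values; make record 0/1 pair sit at the mean
        x = np.repeat([2.0, 1.0, 3.0, 0.5, 3.5, 2.0], 2)
        y = np.repeat(np.arange(6.0), 2)
        local = lee_local(x, y, W)
        assert local[0] == pytest.approx(0.0, abs=1e-12)  # lag(x)_0 = 2.0 = xbar


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.integers(min_value=0, max_value=2**32 - 1), st.integers(min_value=6, max_value=12))
def test_lee_oracle_equivalence_and_bound_fuzz(seed, n):
    """Vectorized Lee's L and L_i equal the loop oracle to 1e-12 and the
    global L stays inside [-1, 1] under row-standardised weights."""
    rng = np.random.default_rng(seed)
    coords = np.column_stack([rng.uniform(16, 17, n), rng.uniform(-6, -5, n)])
    x = rng.standard_normal(n)
    y = rng.standard_normal(n)
    W = knn_weights(coords, k=min(4, n - 1))
    L = lee_global(x, y, W)
    L_oracle, local_oracle = brute_force_lee(x, y, W)
    assert L == pytest.approx(L_oracle, abs=1e-12)
    assert lee_local(x, y, W) == pytest.approx(local_oracle, abs=1e-12)
    assert -1.0 - 1e-12 <= L <= 1.0 + 1e-12


class TestLeeMC:
    def test_determinism_under_fixed_seed(self, six_point_fixture):
        coords, x, y = six_point_fixture
        W = knn_weights(coords, k=2)
        a = lee_mc(x, y, W, n_perm=199, seed=5)
        b = lee_mc(x, y, W, n_perm=199, seed=5)
        assert a.p_value == b.p_value
        assert np.array_equal(a.null_sample, b.null_sample)

    def test_pvalue_never_zero_and_alternatives_consistent(self, null_weights_100):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal(100), rng.standard_normal(100)
        for alt in ("two_sided", "greater", "less"):
            r = lee_mc(x, y, null_weights_100, n_perm=99, seed=2, alternative=alt)
            assert 0 < r.p_value <= 1

    def test_min_permutations_enforced(self, null_weights_100):
        rng = np.random.default_rng(1)
        with pytest.raises(Exception):
            lee_mc(rng.standard_normal(100), rng.standard_normal(100),
                   null_weights_100, n_perm=10)

    def test_detects_strong_coregionalization(self, default_cohort):
        from metalscreen import substitute

        c = default_cohort
        W = knn_weights(c.coords(), k=4)
        x = substitute(c.observed["As"]).values
        y = c.covariates["zn"].to_numpy()
        r = lee_mc(x, y, W, n_perm=499, seed=9)
        assert r.L < 0
        assert r.p_value < 0.05


class TestClassifyLocal:
    def test_labels_partition_sites_and_top_site_significant(self, default_cohort):
        from metalscreen import substitute

        c = default_cohort
        W = knn_weights(c.coords(), k=4)
        x = substitute(c.observed["Hg"]).values
        y = c.covariates["se"].to_numpy()
        r = lee_mc(x, y, W, n_perm=499, seed=13, keep_local_null=True)
        p, sig = classify_local(r.local, r.local_null)
        assert p.shape == sig.shape == (c.n,)
        assert np.all((p > 0) & (p <= 1))
        # the site with the largest observed local L under a real positive
        # association must exceed its permutation null
        top = int(np.argmax(r.local))
        assert sig[top]

    def test_null_significant_fraction_near_alpha(self, null_weights_100):
        rng = np.random.default_rng(31)
        fracs = []
        for _ in range(20):
            x, y = rng.standard_normal(100), rng.standard_normal(100)
            r = lee_mc(x, y, null_weights_100, n_perm=199,
                       seed=int(rng.integers(2**31 - 1)), keep_local_null=True)
            _, sig = classify_local(r.local, r.local_null, alpha=0.05)
            fracs.append(sig.mean())
        assert np.mean(fracs) == pytest.approx(0.05, abs=0.03)
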