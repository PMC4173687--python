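"""Spatial weights, Moran's I, OLS and SAR error-model likelihood."""

import numpy as np
import pytest
from scipy import sparse

from lingrisk.spatial import (
    SpatialWeights,
    distance_band_neighbors,
    fit_ols,
    fit_sar_error,
    logdet_sparse_lu,
    moran_correlogram,
    morans_i,
    nagelkerke_r2,
    select_neighborhood,
)
from lingrisk.synthetic import rook_spatial_weights, sar_error_sample


def path_graph_weights():
    adj = sparse.csr_matrix(np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float))
    deg = np.asarray(adj.sum(axis=1)).ravel()
    w = sparse.diags(1 / deg) @ adj
    return SpatialWeights(1.0, adj, w.tocsr(), deg == 0)


class TestDistanceBand:
    def test_collinear_points(self):
        pts = np.array([[0.0, 0.0], [100.0, 0.0], [400.0, 0.0]])
        sw = distance_band_neighbors(pts, 200.0)
        assert sw.adjacency[0, 1] == 1 and sw.adjacency[1, 0] == 1
        assert sw.adjacency[1, 2] == 0 and sw.adjacency[0, 2] == 0
        assert sw.w[0, 1] == pytest.approx(1.0)
        assert sw.w[1, 0] == pytest.approx(1.0)
        assert sw.isolates.tolist() == [False, False, True]

    def test_threshold_below_all_distances(self):
        pts = np.array([[0.0, 0.0], [500.0, 0.0], [0.0, 700.0]])
        sw = distance_band_neighbors(pts, 10.0)
        assert sw.isolates.all()
        assert sw.adjacency.nnz == 0

    def test_matches_brute_force(self, rng):
        pts = rng.uniform(0, 1000, size=(50, 2))
        thr = 220.0
        sw = distance_band_neighbors(pts, thr)
        dense = sw.adjacency.toarray()
        for i in range(50):
            for j in range(50):
                d = np.hypot(*(pts[i] - pts[j]))
                expected = 1.0 if (i != j and d <= thr) else 0.0
                assert dense[i, j] == expected

    def test_row_sums_binary(self, rng):
        pts = rng.uniform(0, 500, size=(30, 2))
        sw = distance_band_neighbors(pts, 150.0)
        sums = np.asarray(sw.w.sum(axis=1)).ravel()
        for s, iso in zip(sums, sw.isolates):
            assert s == pytest.approx(0.0 if iso else 1.0)


class TestMoran:
    def test_path_graph_zero(self):
        res = morans_i([1.0, 2.0, 3.0], path_graph_weights(), permutations=99)
        assert res.i_value == pytest.approx(0.0, abs=1e-14)

    def test_path_graph_minus_one(self):
        res = morans_i([1.0, -1.0, 1.0], path_graph_weights(), permutations=99)
        assert res.i_value == pytest.approx(-1.0, abs=1e-14)

    def test_expectation(self):
        res = morans_i([1.0, -1.0, 1.0], path_graph_weights(), permutations=99)
        assert res.expected == pytest.approx(-0.5)

    def test_matches_direct_double_sum(self, rng):
        sw = rook_spatial_weights(6, 5)
        z = rng.normal(size=30)
        res = morans_i(z, sw, permutations=9)
        zc = z - z.mean()
        w = sw.w.toarray()
        direct = (30 / w.sum()) * (zc @ w @ zc) / (zc @ zc)
        assert res.i_value == pytest.approx(direct, abs=1e-12)

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError):
            morans_i([2.0, 2.0, 2.0], path_graph_weights())

    def test_permutation_p_detects_structure(self):
        sw = rook_spatial_weights(8, 8)
        rng = np.random.default_rng(0)
        smooth = sar_error_sample(sw.w, 0.8, 1.0, rng)
        res = morans_i(smooth, sw, permutations=199, seed=1)
        assert res.i_value > 0.2
        assert res.p_value < 0.05

    def test_correlogram_shape(self, rng):
        pts = rng.uniform(0, 500, size=(40, 2))
        z = rng.normal(size=40)
        cg = moran_correlogram(z, pts, [0, 150, 300, 450], permutations=19)
        assert list(cg.columns) == ["d_lo", "d_hi", "i_value", "p_value", "n_pairs"]
        assert len(cg) == 3


class TestOls:
    def test_exact_linear_fit(self, rng):
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        beta = np.array([2.0, -1.5])
        fit = fit_ols(X @ beta, X)
        assert np.allclose(fit.beta, beta, atol=1e-10)
        assert np.allclose(fit.residuals, 0, atol=1e-10)

    def test_intercept_only_is_mean(self, rng):
        y = rng.normal(size=50)
        fit = fit_ols(y, np.ones((50, 1)))
        assert fit.beta[0] == pytest.approx(y.mean(), abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        X = np.column_stack([np.ones(100), rng.normal(size=(100, 3))])
        y = rng.normal(size=100)
        fit = fit_ols(y, X)
        beta_ne = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(fit.beta, beta_ne, atol=1e-10)

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.normal(size=30)
        X = np.column_stack([np.ones(30), x, 2 * x])
        with pytest.raises(ValueError, match="dup"):
            fit_ols(rng.normal(size=30), X, names=["intercept", "a", "dup"])


class TestSarError:
    def test_lambda_zero_reduces_to_ols(self, rng):
        sw = rook_spatial_weights(5, 5)
        X = np.column_stack([np.ones(25), rng.normal(size=25)])
        y = rng.normal(size=25)
        sar = fit_sar_error(y, X, sw, lam=0.0)
        ols = fit_ols(y, X)
        assert np.allclose(sar.beta, ols.beta, atol=1e-12)

    def test_likelihood_dominates_ols(self, rng):
        sw = rook_spatial_weights(8, 8)
        X = np.column_stack([np.ones(64), rng.normal(size=64)])
        for seed in range(5):
            r = np.random.default_rng(seed)
            u = sar_error_sample(sw.w, 0.6, 1.0, r)
            y = X @ np.array([1.0, -1.0]) + u
            free = fit_sar_error(y, X, sw)
            at_zero = fit_sar_error(y, X, sw, lam=0.0)
            assert free.log_likelihood >= at_zero.log_likelihood - 1e-8

    def test_no_autocorrelation_gives_small_lambda(self):
        sw = rook_spatial_weights(10, 10)
        lams = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = np.column_stack([np.ones(100), r.normal(size=100)])
            y = X @ np.array([0.5, 1.0]) + r.normal(size=100)
            lams.append(fit_sar_error(y, X, sw).lam)
        assert abs(np.mean(lams)) < 0.15

    def test_aic_counts_lambda_and_sigma(self, rng):
        sw = rook_spatial_weights(5, 5)
        X = np.column_stack([np.ones(25), rng.normal(size=25)])
        y = rng.normal(size=25)
        fit = fit_sar_error(y, X, sw)
        assert fit.aic == pytest.approx(-2 * fit.log_likelihood + 2 * (2 + 2))

    def test_logdet_paths_agree(self):
        sw = rook_spatial_weights(20, 20)
        eigs = sw.eigenvalues()
        for lam in (-0.5, 0.0, 0.4, 0.9):
            dense = float(np.sum(np.log(1 - lam * eigs)))
            lu = logdet_sparse_lu(sw.w, lam)
            assert lu == pytest.approx(dense, abs=1e-8)

    def test_sar_residuals_whiter_than_ols(self):
        # residual whitening on SAR-generated data
        sw = rook_spatial_weights(12, 12)
        closer = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = np.column_stack([np.ones(144), r.normal(size=144)])
            u = sar_error_sample(sw.w, 0.7, 1.0, r)
            y = X @ np.array([1.0, -1.0]) + u
            ols = fit_ols(y, X)
            sar = fit_sar_error(y, X, sw)
            i_ols = morans_i(ols.residuals, sw, permutations=9).i_value
            i_sar = morans_i(sar.residuals, sw, permutations=9).i_value
            expected = -1.0 / 143
            closer += abs(i_sar - expected) < abs(i_ols - expected)
        assert closer >= 9


class TestNeighborhoodSelection:
    def test_single_candidate(self, rng):
        pts = rng.uniform(0, 1000, size=(40, 2))
        X = np.column_stack([np.ones(40), rng.normal(size=40)])
        y = rng.normal(size=40)
        d, fit, sw, table = select_neighborhood(y, X, pts, [300.0])
        assert d == 300.0
        assert len(table) == 1

    def test_failed_candidate_tolerated(self, rng):
        pts = rng.uniform(0, 1000, size=(40, 2))
        X = np.column_stack([np.ones(40), rng.normal(size=40)])
        y = rng.normal(size=40)
        # 1 km threshold isolates everything and fails; 400 km works
        d, fit, sw, table = select_neighborhood(y, X, pts, [1.0, 400.0])
        assert d == 400.0
        assert table["error"].notna().sum() == 1

    def test_all_candidates_failing_raises(self, rng):
        pts = rng.uniform(0, 1000, size=(10, 2))
        X = np.ones((10, 1))
        with pytest.raises(ValueError):
            select_neighborhood(rng.normal(size=10), X, pts, [0.5, 0.6])

    def test_recovers_generating_neighborhood_scale(self):
        # data generated with 400 km neighbours: the selected threshold
        # should sit within one 50-km step of 400 in most seeds
        rng0 = np.random.default_rng(99)
        pts = rng0.uniform(0, 2000, size=(150, 2))
        sw_true = distance_band_neighbors(pts, 400.0)
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            X = np.column_stack([np.ones(150), r.normal(size=150)])
            u = sar_error_sample(sw_true.w, 0.8, 1.0, r)
            y = X @ np.array([1.0, -1.0]) + u
            d, *_ = select_neighborhood(y, X, pts, [250, 300, 350, 400, 450, 500])
            hits += abs(d - 400.0) <= 50.0
        assert hits >= int(0.8 * n_seeds)


class TestNagelkerke:
    def test_equal_likelihoods_give_zero(self):
        assert nagelkerke_r2(-150.0, -150.0, 100) == pytest.approx(0.0)

    def test_closed_form_case(self):
        n, l0, l1 = 100, -150.0, -120.0
        cs = 1 - np.exp(-2 / n * (l1 - l0))
        mx = 1 - np.exp(2 / n * l0)
        assert nagelkerke_r2(l1, l0, n) == pytest.approx(cs / mx, abs=1e-12)

    def test_maximal_cox_snell_gives_one(self):
        # a fit reaching the saturated likelihood (logL = 0)
        assert nagelkerke_r2(0.0, -50.0, 40) == pytest.approx(1.0)

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            nagelkerke_r2(-1.0, -2.0, 0)
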