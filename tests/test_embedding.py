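import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from genoanat import (
    TsneConfig,
    calibrate_affinities,
    kl_cost,
    kmeans,
    low_dim_affinities,
    pairwise_sq_dists,
    run_pca,
    run_tsne,
    score_all,
    tsne_gradient,
)
from genoanat.embedding import _student_t_q
from genoanat.exceptions import DomainError, ValidationError

from conftest import blobs


# ---------------------------------------------------------------------------
# pairwise squared distances


class TestPairwiseSqDists:
    def test_two_points_arithmetic(self):
        D = pairwise_sq_dists(np.array([[0.0], [3.0]]))
        assert D[0, 1] == D[1, 0] == 9.0
        assert D[0, 0] == D[1, 1] == 0.0

    def test_matches_brute_force(self, rng):
        X = rng.standard_normal((40, 7))
        D = pairwise_sq_dists(X)
        for i in range(40):
            for j in range(40):
                assert D[i, j] == pytest.approx(((X[i] - X[j]) ** 2).sum(), abs=1e-9)

    def test_duplicate_row_zero_distance(self, rng):
        X = rng.standard_normal((5, 3))
        X[3] = X[1]
        D = pairwise_sq_dists(X)
        assert D[1, 3] == 0.0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            pairwise_sq_dists(np.array([[np.inf, 0.0], [0.0, 1.0]]))


# ---------------------------------------------------------------------------
# affinity calibration


def check_affinity_invariants(aff, perplexity, n):
    P, Pc = aff.P, aff.P_cond
    assert np.allclose(np.diag(P), 0) and np.allclose(np.diag(Pc), 0)
    assert np.abs(Pc.sum(axis=1) - 1).max() < 1e-10
    assert np.allclose(P, P.T)
    assert (P >= 0).all()
    assert abs(P.sum() - 1.0) < 1e-10
    assert np.abs(aff.realized_perplexities() - perplexity).max() < 1e-4


class TestCalibrateAffinities:
    def test_regular_simplex_uniform_rows(self):
        # n one-hot points: all pairwise distances equal, so every row is
        # uniform at any bandwidth and only perplexity n-1 is realizable
        n = 8
        X = np.eye(n)
        D = pairwise_sq_dists(X)
        aff = calibrate_affinities(D, perplexity=n - 1)
        off = aff.P_cond[~np.eye(n, dtype=bool)]
        assert np.allclose(off, 1.0 / (n - 1))
        with pytest.raises(DomainError):
            calibrate_affinities(D, perplexity=n - 0.5)

    def test_two_points(self):
        D = pairwise_sq_dists(np.array([[0.0], [2.0]]))
        aff = calibrate_affinities(D, perplexity=1.0)
        assert aff.P[0, 1] == pytest.approx(0.5)
        assert aff.P[1, 0] == pytest.approx(0.5)

    def test_random_data_realizes_perplexity(self, rng):
        X = rng.standard_normal((20, 5))
        aff = calibrate_affinities(pairwise_sq_dists(X), perplexity=5.0)
        check_affinity_invariants(aff, 5.0, 20)

    def test_sigmas_match_beta_grid_oracle(self, rng):
        """Brute-force scan over a fine log-spaced beta grid per row."""
        X = rng.standard_normal((20, 5))
        D = pairwise_sq_dists(X)
        aff = calibrate_affinities(D, perplexity=5.0)
        betas = np.logspace(-4, 4, 20001)
        for i in range(20):
            d = np.delete(D[i], i)
            best, best_err = None, np.inf
            for b in betas:
                logit = -b * d
                logit -= logit.max()
                p = np.exp(logit)
                p /= p.sum()
                H = -(p[p > 0] * np.log(p[p > 0])).sum()
                err = abs(H - np.log(5.0))
                if err < best_err:
                    best, best_err = b, err
            sigma_oracle = np.sqrt(1.0 / (2.0 * best))
            assert aff.sigmas[i] == pytest.approx(sigma_oracle, rel=2e-3)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.integers(min_value=10, max_value=80), st.integers(0, 2**31 - 1))
    def test_invariants_property(self, n, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, 6)) * rng.uniform(0.1, 10)
        perp = min(30.0, n / 2)
        aff = calibrate_affinities(pairwise_sq_dists(X), perp)
        check_affinity_invariants(aff, perp, n)


# ---------------------------------------------------------------------------
# low-dimensional affinities and cost


class TestLowDimAffinities:
    def test_two_points_forced_half(self, rng):
        Q = low_dim_affinities(rng.standard_normal((2, 2)))
        assert Q[0, 1] == pytest.approx(0.5)

    def test_collinear_kernel_monotone(self):
        Q = low_dim_affinities(np.array([[0.0], [1.0], [2.0]]))
        assert Q[0, 1] > Q[0, 2]

    def test_matches_brute_force(self, rng):
        Y = rng.standard_normal((30, 2))
        Q = low_dim_affinities(Y)
        denom = 0.0
        for k in range(30):
            for l in range(30):
                if k != l:
                    denom += 1.0 / (1.0 + ((Y[k] - Y[l]) ** 2).sum())
        for i in range(30):
            for j in range(30):
                expect = 0.0 if i == j else (1.0 / (1.0 + ((Y[i] - Y[j]) ** 2).sum())) / denom
                assert Q[i, j] == pytest.approx(expect, abs=1e-12)
        assert abs(Q.sum() - 1.0) < 1e-10

    def test_single_point_rejected(self):
        with pytest.raises(DomainError):
            low_dim_affinities(np.zeros((1, 2)))


class TestKlCost:
    def test_zero_iff_equal(self, rng):
        Q = low_dim_affinities(rng.standard_normal((10, 2)))
        assert kl_cost(Q, Q) == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_summation(self, rng):
        n = 12
        P = np.full((n, n), 1.0 / (n * (n - 1)))
        np.fill_diagonal(P, 0.0)
        Q = low_dim_affinities(rng.standard_normal((n, 2)))
        direct = sum(
            P[i, j] * np.log(P[i, j] / Q[i, j])
            for i in range(n) for j in range(n) if i != j
        )
        assert kl_cost(P, Q) == pytest.approx(direct, abs=1e-12)

    def test_nonnegative_and_asymmetric(self, rng):
        P = low_dim_affinities(rng.standard_normal((15, 2)))
        Q = low_dim_affinities(rng.standard_normal((15, 2)))
        assert kl_cost(P, Q) >= 0.0
        assert kl_cost(P, Q) != pytest.approx(kl_cost(Q, P), abs=1e-6)

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            kl_cost(np.zeros((3, 3)), np.zeros((4, 4)))


# ---------------------------------------------------------------------------
# gradient


def random_P(rng, n):
    A = rng.random((n, n))
    A = (A + A.T) / 2.0
    np.fill_diagonal(A, 0.0)
    return A / A.sum()


class TestTsneGradient:
    def test_matches_finite_differences(self, rng):
        """Central finite differences of the KL cost, 20 random instances."""
        for _ in range(20):
            n, m = 10, 2
            P = random_P(rng, n)
            Y = rng.standard_normal((n, m))
            Q, W = _student_t_q(Y)
            g = tsne_gradient(P, W, Q, Y)
            h = 1e-6
            num = np.zeros_like(Y)
            for i in range(n):
                for t in range(m):
                    Yp, Ym = Y.copy(), Y.copy()
                    Yp[i, t] += h
                    Ym[i, t] -= h
                    num[i, t] = (kl_cost(P, low_dim_affinities(Yp))
                                 - kl_cost(P, low_dim_affinities(Ym))) / (2 * h)
            denom = max(np.linalg.norm(num), 1e-12)
            assert np.linalg.norm(g - num) / denom < 1e-5

    def test_symmetric_configuration_zero_gradient(self):
        # equilateral triangle with uniform P: Q matches P by symmetry
        ang = np.array([0.0, 2 * np.pi / 3, 4 * np.pi / 3])
        Y = np.column_stack([np.cos(ang), np.sin(ang)])
        P = np.full((3, 3), 1.0 / 6)
        np.fill_diagonal(P, 0.0)
        Q, W = _student_t_q(Y)
        g = tsne_gradient(P, W, Q, Y)
        assert np.abs(g).max() < 1e-12

    def test_zero_gradient_at_derivative_free_optimum(self, rng):
        """Nelder-Mead (gradient-free) minimization of the KL cost on a tiny
        n=3 instance; the analytic gradient must vanish at its optimum."""
        from scipy.optimize import minimize

        P = random_P(rng, 3)

        def cost(flat):
            return kl_cost(P, low_dim_affinities(flat.reshape(3, 2)))

        res = minimize(cost, rng.standard_normal(6), method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000})
        Y = res.x.reshape(3, 2)
        Q, W = _student_t_q(Y)
        g = tsne_gradient(P, W, Q, Y)
        assert np.linalg.norm(g) < 1e-6


# ---------------------------------------------------------------------------
# full runs


class TestRunTsne:
    def test_seeded_determinism(self, rng):
        X = rng.standard_normal((40, 6))
        cfg = TsneConfig(perplexity=10, n_iter=100, seed=5)
        e1 = run_tsne(X, 2, cfg)
        e2 = run_tsne(X, 2, cfg)
        np.testing.assert_array_equal(e1.Y, e2.Y)
        assert e1.final_cost == e2.final_cost

    def test_kl_decreases_from_init(self, rng):
        X, _ = blobs(rng, 50, np.eye(3)[:, :2] * 20, sd=1.0)
        X = np.hstack([X, rng.standard_normal((150, 18)) * 0.1])
        cfg = TsneConfig(n_iter=300, seed=2)
        emb = run_tsne(X, 2, cfg)
        # KL at the (seeded) initialization
        D = pairwise_sq_dists(X)
        P = calibrate_affinities(D, cfg.perplexity).P
        Y0 = np.random.default_rng(cfg.seed).normal(0, cfg.init_sd, (150, 2))
        kl0 = kl_cost(np.maximum(P, cfg.min_prob_floor), low_dim_affinities(Y0))
        assert emb.final_cost < kl0

    def test_blob_recovery(self, rng):
        centers = np.zeros((3, 50))
        centers[1, 0] = 30.0
        centers[2, 1] = 30.0
        X, y = blobs(rng, 100, centers, sd=3.0)
        emb = run_tsne(X, 2, TsneConfig(n_iter=400, seed=0))
        res = kmeans(emb.Y, 3, restarts=10, seed=0)
        assert score_all(y, res.labels).ari >= 0.95

    def test_too_few_points(self):
        with pytest.raises(DomainError):
            run_tsne(np.zeros((3, 2)), 2)

    def test_infeasible_perplexity_propagates(self, rng):
        X = rng.standard_normal((10, 3))
        with pytest.raises(DomainError):
            run_tsne(X, 2, TsneConfig(perplexity=30))


class TestRunPca:
    def test_component_variances_ordered(self, rng):
        X = rng.standard_normal((50, 8)) * np.arange(1, 9)
        emb = run_pca(X, 5)
        v = emb.Y.var(axis=0)
        assert all(v[i] >= v[i + 1] - 1e-12 for i in range(4))

    def test_exact_for_low_rank_data(self, rng):
        # data in a 3-D affine subspace of R^10: pairwise geometry is
        # reproduced exactly by the 3 leading components
        B = rng.standard_normal((3, 10))
        Z = rng.standard_normal((30, 3))
        X = Z @ B + rng.standard_normal(10)
        emb = run_pca(X, 3)
        Xc = X - X.mean(0)
        np.testing.assert_allclose(emb.Y @ emb.Y.T, Xc @ Xc.T, atol=1e-8)

    def test_matches_covariance_eigendecomposition_oracle(self, rng):
        X = rng.standard_normal((40, 8))
        emb = run_pca(X, 4)
        Xc = X - X.mean(0)
        C = Xc.T @ Xc / 1.0
        w, V = np.linalg.eigh(C)
        order = np.argsort(w)[::-1]
        V = V[:, order]
        Yo = Xc @ V[:, :4]
        for j in range(4):
            s = np.sign(np.dot(Yo[:, j], emb.Y[:, j]))
            np.testing.assert_allclose(emb.Y[:, j], s * Yo[:, j], atol=1e-8)

    def test_m_too_large(self, rng):
        with pytest.raises(DomainError):
            run_pca(rng.standard_normal((5, 3)), 4)
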