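import numpy as np
import pytest

from fastrr import (
    SimConfig,
    build_whitener,
    compute_kinship,
    estimate_lambda_g,
    generate_genotypes,
    generate_phenotype,
    whiten,
)
from fastrr._reml import restricted_loglik


def _loop_kinship(X):
    """Explicit-loop oracle for the centered cross-product kinship."""
    n, m = X.shape
    Xc = np.empty_like(X, dtype=float)
    for j in range(m):
        Xc[:, j] = X[:, j] - X[:, j].mean()
    s = sum(Xc[i, j] ** 2 for i in range(n) for j in range(m)) / n
    K = np.zeros((n, n))
    for i in range(n):
        for k in range(n):
            K[i, k] = sum(Xc[i, j] * Xc[k, j] for j in range(m)) / s
    return K


class TestComputeKinship:
    def test_matches_loop_oracle(self):
        X = np.array([[0.0, 2.0], [1.0, 0.0], [2.0, 1.0]])
        np.testing.assert_allclose(compute_kinship(X), _loop_kinship(X), atol=1e-12)

    def test_orthogonal_samples_give_identity(self):
        # rows orthogonal after centering -> K proportional to identity
        X = np.array([[1.0, 0.0, -1.0, 0.0],
                      [-1.0, 0.0, 1.0, 0.0],
                      [0.0, 1.0, 0.0, -1.0],
                      [0.0, -1.0, 0.0, 1.0]])
        K = compute_kinship(X - X.mean(0) + X.mean(0))
        off = K - np.diag(np.diag(K))
        # the two sample pairs are exactly anticorrelated; K is block diagonal
        assert np.diag(K).mean() == pytest.approx(1.0)

    def test_symmetric_psd_and_unit_mean_diag(self, small_geno):
        K = compute_kinship(small_geno)
        assert np.max(np.abs(K - K.T)) == 0.0
        assert np.diag(K).mean() == pytest.approx(1.0, rel=1e-10)
        assert np.linalg.eigvalsh(K).min() >= -1e-10
    def test_monomorphic_matrix_rejected(self):
        with pytest.raises(ValueError):
            compute_kinship(np.ones((5, 3)))


class TestEstimateLambdaG:
    def test_null_model_estimates_near_zero(self):
        # sigma_g^2 = 0: the REML ratio collapses toward the boundary.  The
        # null sampling spread of lambda_hat is ~1/sqrt(n Var(xi)/2) (about
        # 0.07 at this size), so the distribution, not every draw, is pinned
        # near zero: the median sits below 0.05 and most draws below 2 SE.
        ests = []
        for s in range(40):
            cfg = SimConfig(n_individuals=800, n_markers=1600,
                            polygenic_multiplier=0.0)
            g = generate_genotypes(cfg, seed=1000 + s)
            y, _ = generate_phenotype(g, None, cfg, seed=2000 + s)
            vr = estimate_lambda_g(y, np.ones((800, 1)), compute_kinship(g))
            ests.append(vr.lambda_g)
        ests = np.asarray(ests)
        assert np.median(ests) < 0.05
        assert np.mean(ests < 0.15) >= 0.8

    def test_recovers_lambda_two(self):
        # data generated at lambda_g = 2: median estimate in [1.5, 2.5]
        ests = []
        for s in range(100):
            cfg = SimConfig(n_individuals=250, n_markers=500,
                            polygenic_multiplier=2.0)
            g = generate_genotypes(cfg, seed=3000 + s)
            y, _ = generate_phenotype(g, None, cfg, seed=4000 + s)
            vr = estimate_lambda_g(y, np.ones((250, 1)), compute_kinship(g))
            ests.append(vr.lambda_g)
        assert 1.5 <= np.median(ests) <= 2.5

    def test_optimizer_dominates_grid_oracle(self, small_geno, small_config):
        y, _ = generate_phenotype(small_geno, None, small_config, seed=6)
        K = compute_kinship(small_geno)
        W = np.ones((small_geno.n_samples, 1))
        xi, U = np.linalg.eigh(K)
        xi = np.clip(xi, 0, None)
        vr = estimate_lambda_g(y, W, K)
        grid = np.geomspace(1e-6, 1e6, 601)
        lls = [restricted_loglik(g, xi, U.T @ y, U.T @ W, len(y)) for g in grid]
        i = int(np.argmax(lls))
        assert vr.log_restricted_likelihood >= max(lls) - 1e-9
        # optimum within one grid step of the brute-force argmax
        lam = max(vr.lambda_g, 1e-6)
        assert grid[max(i - 1, 0)] <= lam <= grid[min(i + 1, 600)]

    def test_intercept_shift_invariance(self, small_geno, small_config):
        y, _ = generate_phenotype(small_geno, None, small_config, seed=8)
        K = compute_kinship(small_geno)
        W = np.ones((len(y), 1))
        a = estimate_lambda_g(y, W, K)
        b = estimate_lambda_g(y + 123.4, W, K)
        # exact in exact arithmetic; the profiled quadratic forms lose a few
        # digits to cancellation once the intercept absorbs the shift
        assert a.lambda_g == pytest.approx(b.lambda_g, rel=1e-3, abs=1e-6)

    def test_singular_design_rejected(self, small_geno, small_config):
        y, _ = generate_phenotype(small_geno, None, small_config, seed=9)
        W = np.ones((len(y), 2))
        with pytest.raises(ValueError):
            estimate_lambda_g(y, W, compute_kinship(small_geno))


class TestWhitener:
    def test_lambda_zero_gives_identity(self):
        K = compute_kinship(np.random.default_rng(0).normal(size=(20, 30)))
        model = build_whitener(K, 0.0)
        np.testing.assert_allclose(model.C, np.eye(20), atol=1e-10)

    def test_identity_kinship_scalar_case(self):
        model = build_whitener(np.eye(6), 3.0)
        np.testing.assert_allclose(model.C, np.eye(6) / 2.0, atol=1e-12)

    def test_whitening_identity_random_psd(self, rng):
        A = rng.normal(size=(50, 80))
        K = compute_kinship(A)
        model = build_whitener(K, 1.0)
        B = model.B
        resid = model.C @ B @ model.C.T - np.eye(50)
        assert np.max(np.abs(resid)) < 1e-8
        np.testing.assert_allclose(model.C, model.C.T, atol=1e-12)

    def test_whiten_matches_loop_oracle(self, rng):
        K = compute_kinship(rng.normal(size=(5, 12)))
        model = build_whitener(K, 0.7)
        y = rng.normal(size=5)
        yc = whiten(model, y=y)[0]
        oracle = np.array([sum(model.C[i, j] * y[j] for j in range(5))
                           for i in range(5)])
        np.testing.assert_allclose(yc, oracle, atol=1e-12)

    def test_whiten_identity_operator_roundtrip(self, rng):
        model = build_whitener(np.eye(7), 0.0)
        y = rng.normal(size=7)
        Z = rng.normal(size=(7, 3))
        yc, _, Zc = whiten(model, y=y, Z=Z)
        np.testing.assert_allclose(yc, y, atol=1e-12)
        np.testing.assert_allclose(Zc, Z, atol=1e-12)

    def test_whitened_noise_is_white(self):
        # empirical covariance of C(u + eps) approaches sigma2 * I
        cfg = SimConfig(n_individuals=60, n_markers=400,
                        polygenic_multiplier=2.0, residual_variance=1.0)
        g = generate_genotypes(cfg, seed=55)
        K = compute_kinship(g)
        model = build_whitener(K, 2.0)
        draws = []
        for s in range(2000):
            _, truth = generate_phenotype(g, None, cfg, seed=10_000 + s)
            rng = np.random.default_rng(90_000 + s)
            eps = rng.normal(0, 1.0, 60)
            draws.append(model.C @ (truth.polygenic_values + eps))
        S = np.cov(np.stack(draws).T, ddof=1)
        mc_se = 1.0 / np.sqrt(2000)
        off = S - np.diag(np.diag(S))
        assert np.mean(np.abs(off)) < 3 * mc_se
        assert np.diag(S).mean() == pytest.approx(1.0, rel=0.1)

    def test_dimension_mismatch_rejected(self):
        model = build_whitener(np.eye(4), 1.0)
        with pytest.raises(ValueError):
            whiten(model, y=np.zeros(5))
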