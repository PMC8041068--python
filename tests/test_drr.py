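import numpy as np
import pytest
from scipy import stats

from fastrr import (
    call_significant,
    deshrink,
    estimate_ridge_components,
    fit_drr,
    orr_blup,
    wald_test,
)
from fastrr._reml import restricted_loglik


def _dense_orr_oracle(y, W, Z, lam, sigma2):
    """Explicit-inverse computation of the ridge BLUP and its variance.

    Uses the n x n form of H and the fixed-effects-absorbed projection
    P = H^-1 - H^-1 W (W^T H^-1 W)^-1 W^T H^-1.
    """
    n = len(y)
    H = lam * (Z @ Z.T) + np.eye(n)
    Hi = np.linalg.inv(H)
    P = Hi - Hi @ W @ np.linalg.inv(W.T @ Hi @ W) @ W.T @ Hi
    gamma = lam * (Z.T @ P @ y)
    d = lam * np.diag(Z.T @ P @ Z)
    var = sigma2 * lam * (1.0 - d)
    return gamma, var, d


def _simulate(n=120, q=6, seed=0, effect=None):
    rng = np.random.default_rng(seed)
    Z = rng.choice([-1.0, 1.0], size=(n, q))
    gamma = np.zeros(q) if effect is None else effect
    y = 5.0 + Z @ gamma + rng.normal(0, 1.0, n)
    W = np.ones((n, 1))
    return y, W, Z


class TestEstimateRidgeComponents:
    def test_recovers_marker_variance(self):
        # gamma_k ~ N(0, 0.04), sigma2 = 1: phi2 estimates cluster near 0.04
        ests = []
        for s in range(60):
            rng = np.random.default_rng(500 + s)
            n, q = 1000, 100
            Z = rng.choice([-1.0, 1.0], size=(n, q))
            gamma = rng.normal(0, 0.2, q)
            y = 2.0 + Z @ gamma + rng.normal(0, 1.0, n)
            comp = estimate_ridge_components(y, np.ones((n, 1)), Z)
            ests.append(comp.phi2)
        assert 0.02 <= np.median(ests) <= 0.06

    def test_null_variance_small(self):
        # pure-noise phenotype: the fitted marker variance mass is negligible
        vals = []
        for s in range(60):
            y, W, Z = _simulate(n=500, q=50, seed=900 + s)
            comp = estimate_ridge_components(y, W, Z)
            vals.append(comp.lam * 50 * np.mean(np.var(Z, axis=0)) / comp.sigma2)
        assert np.median(vals) < 0.1

    def test_matches_grid_oracle(self):
        y, W, Z = _simulate(n=150, q=10, seed=3, effect=np.full(10, 0.4))
        comp = estimate_ridge_components(y, W, Z)
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        xi = s * s
        yt, Wt = U.T @ y, U.T @ W
        grid = np.geomspace(1e-6, 1e6, 601)
        lls = [restricted_loglik(g, xi, yt, Wt, len(y),
                                 syy_p=y @ y - yt @ yt,
                                 swy_p=W.T @ y - Wt.T @ yt,
                                 sww_p=W.T @ W - Wt.T @ Wt) for g in grid]
        i = int(np.argmax(lls))
        assert comp.loglik >= max(lls) - 1e-9
        assert grid[max(i - 1, 0)] <= comp.lam <= grid[min(i + 1, 600)]

    def test_empty_or_degenerate_design_rejected(self):
        y, W, _ = _simulate()
        with pytest.raises(ValueError):
            estimate_ridge_components(y, W, np.empty((len(y), 0)))
        with pytest.raises(ValueError):
            estimate_ridge_components(y, W, np.zeros((len(y), 3)))


class TestOrrBlup:
    def test_matches_dense_oracle(self):
        # q=2, n=6 toy system against the explicit-inverse computation
        rng = np.random.default_rng(8)
        y = rng.normal(size=6)
        W = np.ones((6, 1))
        Z = rng.choice([-1.0, 1.0], size=(6, 2))
        lam, sigma2 = 0.7, 1.3
        alpha_gls = np.linalg.solve(
            W.T @ np.linalg.solve(lam * Z @ Z.T + np.eye(6), W),
            W.T @ np.linalg.solve(lam * Z @ Z.T + np.eye(6), y),
        )
        g, v = orr_blup(y, W, Z, alpha_gls, lam, sigma2)
        g0, v0, _ = _dense_orr_oracle(y, W, Z, lam, sigma2)
        np.testing.assert_allclose(g, g0, atol=1e-10)
        np.testing.assert_allclose(v, v0, atol=1e-10)

    def test_lambda_zero_shrinks_everything(self):
        y, W, Z = _simulate(q=4)
        g, v = orr_blup(y, W, Z, np.array([y.mean()]), 0.0)
        np.testing.assert_array_equal(g, 0.0)
        np.testing.assert_array_equal(v, 0.0)

    def test_posterior_no_wider_than_prior(self):
        y, W, Z = _simulate(n=200, q=20, seed=5, effect=np.full(20, 0.3))
        lam, sigma2 = 0.05, 1.0
        alpha = np.array([y.mean()])
        _, v = orr_blup(y, W, Z, alpha, lam, sigma2)
        assert np.all(v <= lam * sigma2 + 1e-12)

    def test_dual_formula_agreement(self):
        # d from 1 - posterior/prior equals d from lam Z^T P Z
        rng = np.random.default_rng(13)
        n, q = 40, 12
        y = rng.normal(size=n)
        W = np.column_stack([np.ones(n), rng.normal(size=n)])
        Z = rng.normal(size=(n, q))
        lam, sigma2 = 0.3, 2.0
        phi2 = lam * sigma2
        H = lam * Z @ Z.T + np.eye(n)
        Hi = np.linalg.inv(H)
        alpha = np.linalg.solve(W.T @ Hi @ W, W.T @ Hi @ y)
        g, v = orr_blup(y, W, Z, alpha, lam, sigma2)
        d_from_var = 1.0 - v / phi2
        _, _, d_oracle = _dense_orr_oracle(y, W, Z, lam, sigma2)
        np.testing.assert_allclose(d_from_var, d_oracle, atol=1e-8)


class TestDeshrink:
    def test_fully_measured_effect_unchanged(self):
        d, g, v, meas = deshrink(np.array([0.4]), np.array([0.0]), phi2=0.5)
        assert d[0] == 1.0
        assert g[0] == 0.4
        assert v[0] == 0.0
        assert meas[0]

    def test_half_measured_arithmetic(self):
        phi2 = 0.8
        d, g, v, meas = deshrink(np.array([0.5]), np.array([phi2 / 2]), phi2)
        assert d[0] == pytest.approx(0.5)
        assert g[0] == pytest.approx(1.0)
        assert v[0] == pytest.approx(phi2)

    def test_unmeasured_marker_flagged(self):
        phi2 = 1.0
        d, g, v, meas = deshrink(np.array([0.2, 0.3]),
                                 np.array([phi2 * (1 - 1e-12), 0.5]), phi2)
        assert not meas[0] and meas[1]
        assert g[0] == 0.0 and np.isinf(v[0])

    def test_single_marker_drr_equals_ols(self):
        # Woodbury identity: q=1 with intercept-only W collapses to the
        # least-squares slope for any lam > 0
        rng = np.random.default_rng(4)
        n = 50
        z = rng.choice([-1.0, 1.0], size=n)
        y = 3.0 + 0.6 * z + rng.normal(0, 1.0, n)
        W = np.ones((n, 1))
        zc = z - z.mean()
        ols = (zc @ y) / (zc @ zc)
        for lam in (1e-4, 0.05, 1.0, 50.0):
            H = lam * np.outer(z, z) + np.eye(n)
            Hi = np.linalg.inv(H)
            alpha = np.linalg.solve(W.T @ Hi @ W, W.T @ Hi @ y)
            g, v = orr_blup(y, W, z, alpha, lam, 1.0)
            _, g_drr, _, _ = deshrink(g, v, phi2=lam * 1.0)
            assert g_drr[0] == pytest.approx(ols, abs=1e-8)

    def test_deshrinking_enlarges_magnitudes(self):
        y, W, Z = _simulate(n=300, q=15, seed=21, effect=np.full(15, 0.3))
        fit = fit_drr(y, W, Z)
        ok = fit.measured
        assert np.all(np.abs(fit.gamma_drr[ok]) >= np.abs(fit.gamma_orr[ok]) - 1e-12)

    def test_invalid_phi2(self):
        with pytest.raises(ValueError):
            deshrink(np.zeros(1), np.zeros(1), phi2=0.0)


class TestWaldTest:
    def test_null_effect(self):
        w, p = wald_test(np.array([0.0]), np.array([0.5]))
        assert w[0] == 0.0 and p[0] == 1.0

    def test_five_percent_quantile(self):
        w, p = wald_test(np.array([np.sqrt(3.841459)]), np.array([1.0]))
        assert p[0] == pytest.approx(0.05, abs=1e-6)

    def test_type_one_error_calibration(self):
        # null fits: fraction of W > 3.84 is ~5%
        count, total = 0, 0
        for s in range(40):
            y, W, Z = _simulate(n=300, q=25, seed=7000 + s)
            fit = fit_drr(y, W, Z)
            count += int(np.sum(fit.wald > 3.841459))
            total += fit.n_markers
        assert count / total == pytest.approx(0.05, abs=0.02)

    def test_rescaling_invariance(self):
        # joint rescaling of y and Z leaves the Wald statistic unchanged
        # once lam is re-estimated
        y, W, Z = _simulate(n=250, q=8, seed=11, effect=np.full(8, 0.5))
        f1 = fit_drr(y, W, Z)
        c = 3.7
        f2 = fit_drr(c * y, W, c * Z)
        np.testing.assert_allclose(f1.wald, f2.wald, rtol=1e-5)


class TestCallSignificant:
    def test_threshold_arithmetic(self):
        det, thr = call_significant(np.array([1e-6, 1e-3]), 100, alpha=0.05)
        assert thr == pytest.approx(5e-4)
        np.testing.assert_array_equal(det, [0])

    def test_empty_model(self):
        det, thr = call_significant(np.array([]), 0)
        assert len(det) == 0

    def test_all_null(self):
        det, _ = call_significant(np.ones(10), 10)
        assert len(det) == 0
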