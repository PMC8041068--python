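"""Stage 3 of FastRR: deshrinking ridge regression on the selected markers.

The multi-locus model on the q screened candidates is

    y = W alpha + Z gamma + eps,   gamma_k ~ N(0, phi^2) i.i.d.,
    eps ~ MVN(0, sigma2 I),

with a single shared marker-effect variance phi^2, so only two variance
components are estimated.  Writing lam = phi^2 / sigma2 and
H = lam Z Z^T + I:

    gamma_ORR  = lam Z^T H^{-1} (y - W alpha) = lam Z^T P y   (ridge BLUP)
    var(gamma_ORR_k | y) = phi^2 (1 - d_k)                    (posterior variance)
    d_k = 1 - var(gamma_ORR_k | y) / phi^2 = lam Z_k^T P Z_k

where P = H^{-1} - H^{-1} W (W^T H^{-1} W)^{-1} W^T H^{-1} absorbs the
estimated fixed effects (alpha is GLS, so H^{-1}(y - W alpha) = P y; the
projection also propagates the uncertainty of alpha into the posterior
variance, which makes the single-marker deshrunk estimate collapse exactly
to the ordinary least-squares slope).

d_k is the well-measurement factor (effective degree of freedom) of marker
k.  Deshrinking divides both the BLUP effect and its variance by d_k:

    gamma_DRR_k = gamma_ORR_k / d_k,
    var(gamma_DRR_k) = var(gamma_ORR_k | y) / d_k,
    W_k = gamma_DRR_k^2 / var(gamma_DRR_k) ~ chi^2_1 under gamma_k = 0.

All heavy algebra runs through the thin SVD of Z, which is the n x n and
q x q (Woodbury) forms of H at once and stays cheap for q << n or q >> n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import _reml

__all__ = [
    "RidgeComponents",
    "DrrFit",
    "estimate_ridge_components",
    "ridge_components_fixed_phi2",
    "orr_blup",
    "deshrink",
    "wald_test",
    "call_significant",
    "fit_drr",
]

D_FLOOR = 1e-8  # below this the deshrunk quantities are numerically meaningless


@dataclass
class RidgeComponents:
    """REML variance components of the multi-locus ridge model."""

    phi2: float
    sigma2: float
    lam: float            # phi^2 / sigma2
    alpha: np.ndarray
    loglik: float
    at_bound: bool = False


@dataclass
class DrrFit:
    """Full stage-3 fit for the q selected markers."""

    components: RidgeComponents
    gamma_orr: np.ndarray
    var_orr: np.ndarray
    d: np.ndarray
    gamma_drr: np.ndarray
    var_drr: np.ndarray
    wald: np.ndarray
    p_value: np.ndarray
    measured: np.ndarray       # d_k above the stability floor
    n_markers: int

    @property
    def phi2(self):
        return self.components.phi2

    @property
    def sigma2(self):
        return self.components.sigma2

    @property
    def alpha(self):
        return self.components.alpha


def _design(y, W, Z):
    y = np.asarray(y, dtype=float).ravel()
    W = np.atleast_2d(np.asarray(W, dtype=float))
    if W.shape[0] != len(y):
        W = W.T
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if Z.shape[0] != len(y) or W.shape[0] != len(y):
        raise ValueError("y, W and Z row counts differ")
    return y, W, Z


def estimate_ridge_components(y, W, Z, *, bounds=_reml.DEFAULT_BOUNDS,
                              grid_points=121, svd=None) -> RidgeComponents:
    """REML fit of (phi^2, sigma2) and GLS alpha for the multi-locus model.

    One thin SVD of Z gives the eigenbasis of Z Z^T; the restricted
    likelihood is then maximized over lam = phi^2 / sigma2 in one dimension.
    """
    y, W, Z = _design(y, W, Z)
    n, c = W.shape
    if Z.shape[1] == 0:
        raise ValueError("no selected markers: stage 3 cannot run")
    if not np.any(np.ptp(Z, axis=0) > 0) and not np.any(Z[0] != 0):
        raise ValueError("selected marker matrix is identically zero")
    if np.linalg.matrix_rank(W) < c:
        raise ValueError("fixed-effect design W is rank deficient")
    if svd is None:
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    else:
        U, s, Vt = svd
    xi = s * s
    yt = U.T @ y
    Wt = U.T @ W
    res = _reml.fit_variance_ratio(
        xi, yt, Wt, n,
        bounds=bounds, grid_points=grid_points,
        syy_p=float(y @ y - yt @ yt),
        swy_p=W.T @ y - Wt.T @ yt,
        sww_p=W.T @ W - Wt.T @ Wt,
    )
    # lam is kept at its (possibly boundary) REML value: under a global null
    # it collapses to the lower bound, where the deshrunk Wald statistics
    # reduce to marginal squared z-scores and stay chi^2_1-calibrated
    return RidgeComponents(
        phi2=res.lam * res.sigma2,
        sigma2=res.sigma2,
        lam=res.lam,
        alpha=res.alpha,
        loglik=res.loglik,
        at_bound=res.at_lower_bound or res.at_upper_bound,
    )


def ridge_components_fixed_phi2(y, W, Z, phi2, *, svd=None, max_iter=50,
                                tol=1e-10) -> RidgeComponents:
    """Profile sigma2 by REML on the selected model at a fixed prior phi2.

    The marker-effect variance phi2 is carried over from the genome-wide
    polygenic fit (every marker shares the same prior variance whether or
    not it survived screening), so only sigma2 is re-estimated here.  The
    REML profile at a fixed ratio lam = phi2 / sigma2 returns a new sigma2,
    which feeds back into lam; the fixed point is reached in a handful of
    iterations.
    """
    y, W, Z = _design(y, W, Z)
    n, c = W.shape
    if Z.shape[1] == 0:
        raise ValueError("no selected markers: stage 3 cannot run")
    if phi2 < 0:
        raise ValueError("phi2 must be >= 0")
    if svd is None:
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    else:
        U, s, Vt = svd
    xi = s * s
    yt, Wt = U.T @ y, U.T @ W
    syy_p = float(y @ y - yt @ yt)
    swy_p = W.T @ y - Wt.T @ yt
    sww_p = W.T @ W - Wt.T @ Wt
    sigma2 = float(np.var(y, ddof=c))
    alpha = np.full(c, np.nan)
    ll = np.nan
    for _ in range(max_iter):
        lam = phi2 / sigma2
        alpha, s2_new, ll = _reml._profile(lam, xi, yt, Wt, n, syy_p, swy_p, sww_p)
        if abs(s2_new - sigma2) <= tol * max(sigma2, 1e-300):
            sigma2 = float(s2_new)
            break
        sigma2 = float(s2_new)
    return RidgeComponents(
        phi2=float(phi2),
        sigma2=sigma2,
        lam=phi2 / sigma2,
        alpha=np.asarray(alpha, float),
        loglik=float(ll),
        at_bound=False,
    )


def orr_blup(y, W, Z, alpha, lam, sigma2=1.0, *, svd=None):
    """Ridge-regression BLUP effects and their posterior variances.

    Returns (gamma_orr, var_orr) with
    gamma_orr = lam Z^T H^{-1} (y - W alpha) = lam Z^T P y and
    var_orr_k = sigma2 * lam * (1 - lam Z_k^T P Z_k) = phi^2 (1 - d_k),
    evaluated through the thin SVD of Z (algebraically identical to the
    dense n x n or Woodbury q x q forms of H).
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    y, W, Z = _design(y, W, Z)
    q = Z.shape[1]
    if lam == 0:
        return np.zeros(q), np.zeros(q)
    if svd is None:
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    else:
        U, s, Vt = svd
    delta = lam * s * s + 1.0
    scale = 1.0 / delta - 1.0
    r = y - W @ np.asarray(alpha, dtype=float).ravel()
    # H^{-1} v = v + U (1/delta - 1) U^T v for any v
    Hinv_r = r + U @ (scale * (U.T @ r))
    gamma_orr = lam * (Z.T @ Hinv_r)
    # d_k = lam Z_k^T P Z_k; first the H^{-1} part with Z^T U = V diag(s)
    VS = Vt.T * s
    col_ss = np.einsum("ij,ij->j", Z, Z)
    zhz = col_ss + np.einsum("ki,ki,i->k", VS, VS, scale)
    # fixed-effect correction: subtract (Z^T H^-1 W)(W^T H^-1 W)^-1(W^T H^-1 Z)
    Hinv_W = W + U @ (scale[:, None] * (U.T @ W))
    A = W.T @ Hinv_W
    G = Z.T @ Hinv_W                       # q x c
    corr = np.einsum("kc,kc->k", G @ np.linalg.inv(A), G)
    d = lam * (zhz - corr)
    var_orr = sigma2 * lam * np.clip(1.0 - d, 0.0, None)
    return gamma_orr, var_orr


def deshrink(gamma_orr, var_orr, phi2, floor: float = D_FLOOR):
    """Deshrink BLUP effects by the well-measurement factor d_k.

    Returns (d, gamma_drr, var_drr, measured).  Markers whose d_k falls at
    or below ``floor`` are flagged unmeasured (measured=False): their effect
    is essentially unidentified and they are excluded from testing; their
    deshrunk entries are set to 0 effect / infinite variance.
    """
    if phi2 <= 0:
        raise ValueError("phi2 must be > 0 to deshrink")
    gamma_orr = np.asarray(gamma_orr, dtype=float)
    var_orr = np.asarray(var_orr, dtype=float)
    d = 1.0 - var_orr / phi2
    measured = d > floor
    d_safe = np.where(measured, d, 1.0)
    gamma_drr = np.where(measured, gamma_orr / d_safe, 0.0)
    var_drr = np.where(measured, var_orr / d_safe, np.inf)
    return d, gamma_drr, var_drr, measured


def wald_test(gamma_drr, var_drr):
    """Wald chi-square statistics W_k = gamma_DRR_k^2 / var(gamma_DRR_k).

    p_k is the upper tail of chi^2 with one degree of freedom.  Entries with
    infinite variance (unmeasured markers) get W = 0, p = 1.
    """
    gamma_drr = np.asarray(gamma_drr, dtype=float)
    var_drr = np.asarray(var_drr, dtype=float)
    if np.any(var_drr <= 0):
        raise ValueError("var_drr must be positive")
    with np.errstate(invalid="ignore"):
        w = np.where(np.isinf(var_drr), 0.0, gamma_drr**2 / var_drr)
    p = stats.chi2.sf(w, df=1)
    return w, p


def call_significant(p_values, n_model_markers: int, alpha: float = 0.05):
    """Bonferroni call at alpha / (number of markers in the genetic model).

    Returns (detected indices, threshold).  An empty model yields an empty
    set.
    """
    p_values = np.asarray(p_values, dtype=float)
    if n_model_markers <= 0:
        return np.array([], dtype=int), np.nan
    threshold = alpha / n_model_markers
    return np.flatnonzero(p_values < threshold), threshold


def fit_drr(y, W, Z, *, phi2=None, floor=D_FLOOR,
            bounds=_reml.DEFAULT_BOUNDS, grid_points=121) -> DrrFit:
    """Run the full stage-3 chain on the selected design (one SVD).

    With ``phi2`` given, the marker-effect variance is held fixed (the
    genome-wide prior) and only sigma2 is profiled; otherwise both
    components come from the subset REML fit.
    """
    y, W, Z = _design(y, W, Z)
    svd = np.linalg.svd(Z, full_matrices=False)
    if phi2 is None:
        comp = estimate_ridge_components(y, W, Z, bounds=bounds,
                                         grid_points=grid_points, svd=svd)
    else:
        comp = ridge_components_fixed_phi2(y, W, Z, phi2, svd=svd)
    q = Z.shape[1]
    if comp.lam == 0.0:
        # no marker variance at all: every effect shrinks to zero
        zeros = np.zeros(q)
        return DrrFit(comp, zeros, zeros, zeros, zeros,
                      np.full(q, np.inf), zeros, np.ones(q),
                      np.zeros(q, dtype=bool), q)
    gamma_orr, var_orr = orr_blup(y, W, Z, comp.alpha, comp.lam,
                                  comp.sigma2, svd=svd)
    d, gamma_drr, var_drr, measured = deshrink(gamma_orr, var_orr,
                                               comp.phi2, floor=floor)
    w, p = wald_test(gamma_drr, var_drr)
    return DrrFit(comp, gamma_orr, var_orr, d, gamma_drr, var_drr,
                  w, p, measured, q)
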