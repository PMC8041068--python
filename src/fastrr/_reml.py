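"""Restricted-likelihood machinery shared by the kinship and ridge stages.

Both variance-component fits in FastRR reduce to the same one-dimensional
problem: for a model y = W a + g + e with var(y) = s2 * (lam * A + I) and a
symmetric PSD matrix A, profile out ``a`` and ``s2`` and maximize the
restricted log-likelihood over the single ratio ``lam``.  Working in the
eigenbasis of A makes every likelihood evaluation O(n * c^2), so a dense grid
plus Brent refinement is cheap after the one decomposition.

The eigenbasis may be *thin*: when A = Z Z^T for a tall-thin Z, only the
``k = rank(Z)`` informative directions are rotated and the orthogonal
complement (eigenvalue 0, i.e. unit variance) enters through precomputed
cross-products.  ``syy_p``, ``swy_p`` and ``sww_p`` carry those complement
terms; they are zero for a full-rank rotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = ["RemlResult", "restricted_loglik", "fit_variance_ratio"]

DEFAULT_BOUNDS = (1e-6, 1e6)


@dataclass(frozen=True)
class RemlResult:
    """Outcome of a one-dimensional REML fit over a variance ratio."""

    lam: float
    sigma2: float
    alpha: np.ndarray
    loglik: float
    at_lower_bound: bool
    at_upper_bound: bool


def _profile(lam, xi, yt, Wt, n, syy_p, swy_p, sww_p):
    """Profiled quantities at a fixed ratio: (alpha, sigma2, restricted ll)."""
    delta = lam * xi + 1.0
    c = Wt.shape[1]
    WtD = Wt / delta[:, None]
    A = sww_p + WtD.T @ Wt          # W^T H^-1 W
    b = swy_p + WtD.T @ yt          # W^T H^-1 y
    yy = syy_p + yt @ (yt / delta)  # y^T H^-1 y
    alpha = np.linalg.solve(A, b)
    rss = max(yy - b @ alpha, np.finfo(float).tiny)
    sigma2 = rss / (n - c)
    WtW = sww_p + Wt.T @ Wt
    ll = -0.5 * (
        (n - c) * (np.log(2.0 * np.pi * sigma2) + 1.0)
        + np.sum(np.log(delta))
        + np.linalg.slogdet(A)[1]
        - np.linalg.slogdet(WtW)[1]
    )
    return alpha, sigma2, ll


def restricted_loglik(lam, xi, yt, Wt, n, syy_p=0.0, swy_p=None, sww_p=None):
    """Restricted log-likelihood of var(y) = sigma2*(lam*A + I) at ``lam``."""
    Wt = np.atleast_2d(np.asarray(Wt, dtype=float))
    if Wt.shape[0] != len(yt):
        raise ValueError("design rotation does not match response rotation")
    c = Wt.shape[1]
    if swy_p is None:
        swy_p = np.zeros(c)
    if sww_p is None:
        sww_p = np.zeros((c, c))
    return _profile(lam, np.asarray(xi, float), np.asarray(yt, float), Wt, n,
                    float(syy_p), np.asarray(swy_p, float),
                    np.asarray(sww_p, float))[2]


def fit_variance_ratio(
    xi,
    yt,
    Wt,
    n,
    *,
    bounds=DEFAULT_BOUNDS,
    grid_points=121,
    syy_p=0.0,
    swy_p=None,
    sww_p=None,
):
    """Maximize the restricted likelihood over lam on [bounds] (log scale).

    A geometric grid brackets the optimum, Brent's method refines it inside
    the best bracket, and the better of (grid argmax, refined point) is
    returned so the fit always dominates its own grid.
    """
    xi = np.asarray(xi, dtype=float)
    yt = np.asarray(yt, dtype=float)
    Wt = np.asarray(Wt, dtype=float)
    if Wt.ndim == 1:
        Wt = Wt[:, None]
    c = Wt.shape[1]
    if n <= c:
        raise ValueError("need more observations than fixed effects")
    swy_p = np.zeros(c) if swy_p is None else np.asarray(swy_p, float)
    sww_p = np.zeros((c, c)) if sww_p is None else np.asarray(sww_p, float)
    syy_p = float(syy_p)

    def ll(lam):
        return _profile(lam, xi, yt, Wt, n, syy_p, swy_p, sww_p)[2]

    lo, hi = bounds
    grid = np.geomspace(lo, hi, grid_points)
    vals = np.array([ll(g) for g in grid])
    i = int(np.argmax(vals))
    lam_best, ll_best = grid[i], vals[i]

    b_lo = grid[max(i - 1, 0)]
    b_hi = grid[min(i + 1, grid_points - 1)]
    if b_hi > b_lo:
        res = minimize_scalar(
            lambda t: -ll(np.exp(t)),
            bounds=(np.log(b_lo), np.log(b_hi)),
            method="bounded",
            options={"xatol": 1e-10},
        )
        lam_ref = float(np.exp(res.x))
        if -res.fun > ll_best:
            lam_best, ll_best = lam_ref, -res.fun

    alpha, sigma2, _ = _profile(lam_best, xi, yt, Wt, n, syy_p, swy_p, sww_p)
    return RemlResult(
        lam=float(lam_best),
        sigma2=float(sigma2),
        alpha=np.asarray(alpha, float),
        loglik=float(ll_best),
        at_lower_bound=bool(lam_best <= lo * 1.5),
        at_upper_bound=bool(lam_best >= hi / 1.5),
    )
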