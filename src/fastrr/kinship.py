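"""Stage 1 of FastRR: kinship, polygenic variance ratio, and whitening.

The reduced model y = W a + u + eps with u ~ MVN(0, sigma_g^2 K) and
eps ~ MVN(0, sigma2 I) has var(y) = sigma2 (lambda_g K + I) where
lambda_g = sigma_g^2 / sigma2.  The ratio is estimated once by REML on the
eigenbasis of K (a single n x n decomposition followed by one-dimensional
optimization) and frozen.  With B = lambda_g K + I = Q L Q^T, the whitening
operator C = Q L^{-1/2} Q^T satisfies C B C^T = I, so the transformed model

    C y = C W a + C Z gamma + C(u + eps)

has residual covariance sigma2 I and downstream stages can ignore the
polygenic background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import blas as _blas
from scipy.linalg import eigh

from . import _reml
from .genotypes import GenotypeMatrix

__all__ = [
    "KinshipModel",
    "VarianceRatios",
    "compute_kinship",
    "estimate_lambda_g",
    "build_whitener",
    "whiten",
]

EIG_FLOOR = 1e-8  # clipping floor for eigenvalues of B before L^{-1/2}


@dataclass
class VarianceRatios:
    """Variance-component ratios from the reduced (no-marker) model fit.

    ``lambda_gamma`` (the per-marker ratio sigma_gamma^2 / sigma2) is held
    at 0 during screening: unassociated markers contribute no variance, so
    the scan never re-estimates it.
    """

    lambda_g: float
    sigma2: float
    log_restricted_likelihood: float
    lambda_gamma: float = 0.0
    at_bound: bool = False


@dataclass
class KinshipModel:
    """Relatedness matrix with its fitted ratio and whitening operator."""

    K: np.ndarray
    lambda_g: float
    eigvecs: np.ndarray      # Q, shared by K and B = lambda_g K + I
    eigvals_B: np.ndarray    # L, eigenvalues of B (clipped at EIG_FLOOR)
    C: np.ndarray            # Q L^{-1/2} Q^T

    @property
    def B(self) -> np.ndarray:
        return self.lambda_g * self.K + np.eye(self.K.shape[0])


def compute_kinship(geno, dtype=np.float64) -> np.ndarray:
    """Centered cross-product relatedness matrix, scaled to mean diagonal 1.

    K = X_c X_c^T / s with X_c the column-centered genotype matrix and
    s = trace(X_c X_c^T) / n, computed from all markers.  ``dtype`` controls
    the precision of the rank-k update (float32 halves the cost on large
    panels; the result is returned in float64 either way).
    """
    X = geno.matrix if isinstance(geno, GenotypeMatrix) else np.asarray(geno)
    X = np.asarray(X, dtype=dtype)
    n, m = X.shape
    if n < 2:
        raise ValueError("kinship needs at least two samples")
    Xc = np.ascontiguousarray(X - X.mean(axis=0))
    s = float(np.einsum("ij,ij->", Xc, Xc, dtype=np.float64)) / n
    if s <= 0:
        raise ValueError("all markers are monomorphic; kinship undefined")
    syrk = _blas.ssyrk if Xc.dtype == np.float32 else _blas.dsyrk
    Ku = syrk(1.0 / s, Xc)  # upper triangle of Xc Xc^T / s
    K = np.triu(Ku) + np.triu(Ku, 1).T
    return np.asarray(K, dtype=np.float64)


def _eig_psd(K, dtype=np.float64):
    """Eigendecomposition of a PSD kinship matrix with a negativity check.

    ``dtype=float32`` halves the decomposition cost on large panels; the
    spectrum is returned in float64 either way (relative eigenvalue error
    ~1e-6 n, far below the Monte-Carlo noise of anything downstream).
    """
    K = np.asarray(K, dtype=dtype)
    xi, U = eigh(K, driver="evd")
    xi = np.asarray(xi, dtype=np.float64)
    U = np.asarray(U, dtype=np.float64)
    # tolerance covers float32-accumulated kinship round-off; genuinely
    # indefinite user matrices fail it by orders of magnitude
    if xi.min() < -1e-4 * max(xi.max(), 1.0):
        raise np.linalg.LinAlgError(
            f"kinship matrix is not PSD (min eigenvalue {xi.min():.3e})"
        )
    return np.clip(xi, 0.0, None), U


def estimate_lambda_g(
    y,
    W,
    K=None,
    *,
    eig=None,
    bounds=_reml.DEFAULT_BOUNDS,
    grid_points=121,
) -> VarianceRatios:
    """REML estimate of lambda_g = sigma_g^2 / sigma2 under the reduced model.

    Either ``K`` or a precomputed ``eig = (eigenvalues, eigenvectors)`` of K
    must be given.  The fit rotates y and W into the eigenbasis and runs a
    grid-bracketed Brent search on log(lambda_g).
    """
    y = np.asarray(y, dtype=float).ravel()
    W = np.atleast_2d(np.asarray(W, dtype=float))
    if W.shape[0] != len(y):
        W = W.T
    n, c = W.shape
    if np.linalg.matrix_rank(W) < c:
        raise ValueError("fixed-effect design W is rank deficient")
    if n <= c:
        raise ValueError("need more samples than fixed effects")
    if eig is None:
        if K is None:
            raise ValueError("provide K or its eigendecomposition")
        eig = _eig_psd(K)
    xi, U = eig
    res = _reml.fit_variance_ratio(
        xi, U.T @ y, U.T @ W, n, bounds=bounds, grid_points=grid_points
    )
    # a ratio collapsing to the lower bound is an effectively zero polygenic
    # variance, not a boundary pathology; only flag the upper bound
    return VarianceRatios(
        lambda_g=0.0 if res.at_lower_bound else res.lam,
        sigma2=res.sigma2,
        log_restricted_likelihood=res.loglik,
        at_bound=res.at_upper_bound,
    )


def build_whitener(K, lambda_g, *, eig=None, dtype=np.float64) -> KinshipModel:
    """Construct C = Q L^{-1/2} Q^T from B = lambda_g K + I."""
    if lambda_g < 0:
        raise ValueError("lambda_g must be >= 0")
    K = np.asarray(K, dtype=np.float64)
    if eig is None:
        xi, U = _eig_psd(K)
    else:
        xi, U = eig
    lam_B = lambda_g * xi + 1.0
    if np.any(lam_B <= 0):
        bad = lam_B.min()
        lam_B = np.clip(lam_B, EIG_FLOOR, None)
        if bad <= -EIG_FLOOR:
            raise np.linalg.LinAlgError(
                f"whitening matrix B has non-positive eigenvalue {bad:.3e}"
            )
    Uw = np.asarray(U, dtype=dtype)
    scale = np.asarray(1.0 / np.sqrt(lam_B), dtype=dtype)
    C = (Uw * scale) @ Uw.T
    C = (C + C.T) / 2
    return KinshipModel(K=K, lambda_g=float(lambda_g), eigvecs=U,
                        eigvals_B=lam_B, C=C)


def whiten(model: KinshipModel, y=None, W=None, Z=None):
    """Apply the whitening operator to phenotype, design and marker columns.

    Returns (Cy, CW, CZ); entries corresponding to ``None`` inputs are None.
    """
    C = model.C
    n = C.shape[0]
    out = []
    for name, M in (("y", y), ("W", W), ("Z", Z)):
        if M is None:
            out.append(None)
            continue
        A = np.asarray(M)
        if A.shape[0] != n:
            raise ValueError(f"{name} has {A.shape[0]} rows, expected {n}")
        if A.ndim == 1:
            out.append(C @ np.asarray(A, dtype=C.dtype))
        else:
            out.append(C @ np.asarray(A, dtype=C.dtype, order="F" if A.flags.f_contiguous else "C"))
    return tuple(out)
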