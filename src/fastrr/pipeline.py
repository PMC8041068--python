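"""End-to-end FastRR pipeline: whitening -> screening -> deshrinking ridge.

``run_fastrr`` wires the three stages together on a genotype matrix and a
phenotype vector:

1. build (or load) the relatedness matrix K, REML-fit lambda_g on the
   reduced model, and whiten phenotype/design/markers with
   C = Q L^{-1/2} Q^T;
2. marginal correlation scan of the whitened markers against the whitened
   phenotype, keeping markers with p < screen_threshold;
3. deshrinking ridge regression of the *untransformed* phenotype on the
   selected markers (the polygenic background was already used to pick
   candidates and is not modelled again), Wald tests, and a Bonferroni call
   at alpha / q with q the number of markers in the fitted model.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import drr as _drr
from . import kinship as _kinship
from . import screening as _screening
from ._reml import DEFAULT_BOUNDS
from .genotypes import GenotypeMatrix

__all__ = ["FastrrConfig", "GwasResultTable", "run_fastrr"]

log = logging.getLogger("fastrr")

RESULT_COLUMNS = [
    "marker_id", "position", "screen_r", "screen_p", "gamma_orr",
    "gamma_drr", "se_drr", "d", "wald", "p_value", "measured", "significant",
]


@dataclass
class FastrrConfig:
    """Tunable knobs of the pipeline (defaults follow the published run)."""

    screen_threshold: float = 0.01
    alpha: float = 0.05
    bonferroni: str = "model_markers"     # or "all_markers"
    ridge_prior: str = "stage1_prior"     # or "model_reml"
    reml_bounds: tuple = DEFAULT_BOUNDS
    reml_grid_points: int = 121
    d_floor: float = _drr.D_FLOOR
    n_workers: int = 1
    precision: str = "fast"               # float32 whitening gemms; "double" for float64
    stage3_on_whitened: bool = False      # sensitivity analysis only
    seed: int | None = None

    def validate(self):
        if not (0.0 < self.screen_threshold < 1.0):
            raise ValueError("screen_threshold must be in (0, 1)")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.bonferroni not in ("model_markers", "all_markers"):
            raise ValueError("bonferroni must be 'model_markers' or 'all_markers'")
        if self.ridge_prior not in ("stage1_prior", "model_reml"):
            raise ValueError("ridge_prior must be 'stage1_prior' or 'model_reml'")
        if self.n_workers < 1:
            raise ValueError("n_workers must be >= 1")
        if self.precision not in ("fast", "double"):
            raise ValueError("precision must be 'fast' or 'double'")


@dataclass
class GwasResultTable:
    """One row per tested marker plus run-level metadata."""

    table: pd.DataFrame
    lambda_g: float
    sigma2_reduced: float
    n_selected: int
    threshold: float
    metadata: dict = field(default_factory=dict)

    @property
    def detected_positions(self) -> np.ndarray:
        if self.table.empty:
            return np.array([], dtype=np.int64)
        return self.table.loc[self.table["significant"], "position"].to_numpy()

    def to_tsv(self, path):
        with open(path, "w") as fh:
            fh.write(f"# lambda_g: {self.lambda_g:.6g}\n")
            fh.write(f"# sigma2_reduced: {self.sigma2_reduced:.6g}\n")
            fh.write(f"# n_selected: {self.n_selected}\n")
            fh.write(f"# bonferroni_threshold: {self.threshold:.6g}\n")
            for k, v in self.metadata.items():
                fh.write(f"# {k}: {v}\n")
            self.table.to_csv(fh, sep="\t", index=False)


def _empty_table():
    return pd.DataFrame({c: [] for c in RESULT_COLUMNS})


def _align(geno: GenotypeMatrix, y, covariates):
    """Inner-join genotype/phenotype/covariate samples on IDs when present."""
    if isinstance(y, pd.Series) and geno.sample_ids is not None:
        ids = pd.Index(geno.sample_ids.astype(str))
        common = ids.intersection(pd.Index(y.index.astype(str)))
        if covariates is not None and isinstance(covariates, pd.DataFrame):
            common = common.intersection(pd.Index(covariates.index.astype(str)))
        if len(common) == 0:
            raise ValueError("no overlapping sample IDs between inputs")
        dropped = len(ids) - len(common)
        if dropped:
            log.info("dropping %d samples absent from phenotype/covariates", dropped)
        keep = ids.get_indexer(common)
        geno = GenotypeMatrix(
            matrix=geno.matrix[keep],
            marker_ids=geno.marker_ids,
            positions=geno.positions,
            sample_ids=geno.sample_ids[keep],
            maf=geno.maf,
        )
        y = y.loc[common].to_numpy(dtype=float)
        if covariates is not None and isinstance(covariates, pd.DataFrame):
            covariates = covariates.loc[common].to_numpy(dtype=float)
        return geno, y, covariates
    y = np.asarray(y, dtype=float).ravel()
    if len(y) != geno.n_samples:
        raise ValueError("phenotype length does not match genotype sample count")
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.shape[0] != geno.n_samples:
            raise ValueError("covariate rows do not match genotype sample count")
    return geno, y, covariates


def run_fastrr(geno, y, covariates=None, config: FastrrConfig | None = None,
               kinship=None) -> GwasResultTable:
    """Run the three-stage FastRR pipeline and return the result table."""
    config = config or FastrrConfig()
    config.validate()
    if not isinstance(geno, GenotypeMatrix):
        geno = GenotypeMatrix(matrix=np.asarray(geno))
    geno, y, covariates = _align(geno, y, covariates)
    n, m = geno.n_samples, geno.n_markers
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant")
    W = np.ones((n, 1))
    if covariates is not None:
        W = np.column_stack([W, covariates])
    if np.linalg.matrix_rank(W) < W.shape[1]:
        raise ValueError("fixed-effect design (intercept + covariates) is rank deficient")

    dtype = np.float32 if config.precision == "fast" else np.float64
    timings = {}
    t0 = time.perf_counter()

    # stage 1: kinship, lambda_g, whitening
    if kinship is None:
        K = _kinship.compute_kinship(geno, dtype=dtype)
    else:
        K = np.asarray(kinship, dtype=float)
        if K.shape != (n, n):
            raise ValueError("precomputed kinship shape does not match samples")
    eig = _kinship._eig_psd(K, dtype=dtype)
    ratios = _kinship.estimate_lambda_g(
        y, W, eig=eig, bounds=config.reml_bounds,
        grid_points=config.reml_grid_points,
    )
    model = _kinship.build_whitener(K, ratios.lambda_g, eig=eig, dtype=dtype)
    Zall = np.asarray(geno.matrix, dtype=dtype)
    y_c, W_c, Z_c = _kinship.whiten(model, y, W, Zall)
    timings["whitening_s"] = time.perf_counter() - t0
    log.info("stage 1: lambda_g=%.4g sigma2=%.4g", ratios.lambda_g, ratios.sigma2)

    # stage 2: marginal correlation screening
    t0 = time.perf_counter()
    scan = _screening.marginal_scan(y_c, Z_c, n_workers=config.n_workers)
    scan = _screening.select_candidates(scan, config.screen_threshold)
    sel = scan.candidates
    q = len(sel)
    timings["screening_s"] = time.perf_counter() - t0
    log.info("stage 2: %d of %d markers pass p < %g", q, m, config.screen_threshold)

    from . import __version__

    meta = {
        "fastrr_version": __version__,
        "n_samples": n,
        "n_markers": m,
        "screen_threshold": config.screen_threshold,
        "alpha": config.alpha,
        "bonferroni": config.bonferroni,
        "ridge_prior": config.ridge_prior,
        "precision": config.precision,
        **timings,
    }
    if q == 0:
        log.info("empty candidate set: no markers to test")
        return GwasResultTable(_empty_table(), ratios.lambda_g, ratios.sigma2,
                               0, np.nan, meta)

    # stage 3: deshrinking ridge regression on the untransformed data
    t0 = time.perf_counter()
    if config.stage3_on_whitened:
        y3, W3, Z3 = np.asarray(y_c, float), np.asarray(W_c, float), np.asarray(Z_c[:, sel], float)
    else:
        y3, W3, Z3 = y, W, np.asarray(geno.matrix[:, sel], dtype=float)
    phi2 = None
    if config.ridge_prior == "stage1_prior":
        # per-marker share of the genome-wide polygenic variance:
        # sigma_g^2 K = (sigma_g^2 / s) X_c X_c^T, so each marker's prior
        # effect variance is sigma_g^2 / s with s = sum of marker variances
        X = np.asarray(geno.matrix, dtype=np.float64)
        s_scale = float(np.sum(np.mean(X * X, axis=0) - np.mean(X, axis=0) ** 2))
        phi2 = ratios.lambda_g * ratios.sigma2 / s_scale
        if phi2 <= 0:
            # no detectable polygenic variance: keep a vanishing ridge prior
            # so effects stay in the fully deshrunk (marginal) regime
            phi2 = config.reml_bounds[0] * ratios.sigma2
    fit = _drr.fit_drr(
        y3, W3, Z3, phi2=phi2, floor=config.d_floor,
        bounds=config.reml_bounds, grid_points=config.reml_grid_points,
    )
    denom = q if config.bonferroni == "model_markers" else m
    detected, threshold = _drr.call_significant(fit.p_value, denom, config.alpha)
    significant = np.zeros(q, dtype=bool)
    significant[detected] = True
    timings["drr_s"] = time.perf_counter() - t0
    meta.update(timings)
    log.info("stage 3: phi2=%.4g sigma2=%.4g, %d significant at p < %.3g",
             fit.phi2, fit.sigma2, int(significant.sum()), threshold)

    with np.errstate(invalid="ignore"):
        se = np.where(np.isfinite(fit.var_drr), np.sqrt(fit.var_drr), 0.0)
    table = pd.DataFrame({
        "marker_id": geno.marker_ids[sel],
        "position": geno.positions[sel],
        "screen_r": scan.r[sel],
        "screen_p": scan.p[sel],
        "gamma_orr": fit.gamma_orr,
        "gamma_drr": fit.gamma_drr,
        "se_drr": se,
        "d": fit.d,
        "wald": fit.wald,
        "p_value": fit.p_value,
        "measured": fit.measured,
        "significant": significant,
    })
    return GwasResultTable(table, ratios.lambda_g, ratios.sigma2, q,
                           threshold, meta)
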