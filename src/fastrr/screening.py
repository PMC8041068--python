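"""Stage 2 of FastRR: marginal correlation screening on whitened data.

Each whitened marker column is tested for Pearson correlation with the
whitened phenotype; the two-sided p-value comes from
t = r * sqrt((n - 2) / (1 - r^2)) on n - 2 degrees of freedom (the standard
correlation test).  Markers with p strictly below the threshold (default
0.01, deliberately loose so that slight correlations survive) form the
candidate set for the multi-locus ridge stage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from joblib import Parallel, delayed
from scipy import stats

__all__ = ["ScreenResult", "marginal_scan", "select_candidates"]

DEFAULT_THRESHOLD = 0.01


@dataclass
class ScreenResult:
    """Per-marker correlation statistics and (optionally) the selection."""

    r: np.ndarray
    t: np.ndarray
    p: np.ndarray
    n_samples: int
    threshold: float | None = None
    selected: np.ndarray | None = None     # boolean mask, set by selection
    candidates: np.ndarray | None = None   # sorted indices with p < threshold

    @property
    def n_selected(self) -> int:
        return 0 if self.candidates is None else len(self.candidates)

    def to_frame(self, marker_ids=None):
        import pandas as pd

        m = len(self.r)
        d = {
            "marker_id": np.arange(1, m + 1) if marker_ids is None else marker_ids,
            "r": self.r,
            "t": self.t,
            "p": self.p,
        }
        if self.selected is not None:
            d["selected"] = self.selected
        return pd.DataFrame(d)


def _scan_block(yc, Zc, y_center, ssy):
    """Correlation stats for one block of marker columns.

    Each column is reduced with fixed-shape 1-D float64 kernels so the
    result is bit-identical for every block partition and worker count.
    """
    n = len(yc)
    m_blk = Zc.shape[1]
    col_sum = np.empty(m_blk)
    col_ss = np.empty(m_blk)
    num = np.empty(m_blk)
    for j in range(m_blk):
        zj = np.ascontiguousarray(Zc[:, j], dtype=np.float64)
        col_sum[j] = zj.sum()
        col_ss[j] = zj @ zj
        # y_center has mean zero, so the cross term needs no mean correction
        num[j] = zj @ y_center
    ssz = col_ss - col_sum**2 / n          # sum of squares about the mean
    ok = ssz > np.finfo(float).eps * n * np.maximum(col_ss, 1.0)
    r = np.zeros(Zc.shape[1])
    np.divide(num, np.sqrt(ssz * ssy), out=r, where=ok)
    np.clip(r, -1.0, 1.0, out=r)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 0.0))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isinf(t)] = 0.0   # |r| = 1
    p[~ok] = 1.0           # monomorphic / zero-variance markers: never selected
    t[~ok] = 0.0
    return r, t, p


def marginal_scan(y_c, Z_c, n_workers: int = 1, block_size: int | None = None) -> ScreenResult:
    """Pearson correlation scan of every marker column against the phenotype.

    ``n_workers`` parallelizes over marker blocks; results are identical for
    any worker count or block size because each marker's statistic depends
    only on its own column.
    """
    y_c = np.asarray(y_c, dtype=np.float64).ravel()
    n = len(y_c)
    if n < 3:
        raise ValueError("correlation test needs at least 3 samples")
    Z_c = np.asarray(Z_c)
    if Z_c.ndim == 1:
        Z_c = Z_c[:, None]
    if Z_c.shape[0] != n:
        raise ValueError("phenotype and marker matrix row counts differ")
    m = Z_c.shape[1]
    y_center = y_c - y_c.mean()
    ssy = float(y_center @ y_center)
    if ssy <= 0:
        raise ValueError("whitened phenotype is constant")

    if m == 0:
        empty = np.array([])
        return ScreenResult(r=empty, t=empty, p=empty, n_samples=n)
    if block_size is None:
        block_size = m if n_workers == 1 else max(1, -(-m // n_workers))
    starts = list(range(0, m, block_size))
    if n_workers == 1 or len(starts) == 1:
        parts = [_scan_block(y_c, Z_c[:, s:s + block_size], y_center, ssy)
                 for s in starts]
    else:
        parts = Parallel(n_jobs=n_workers)(
            delayed(_scan_block)(y_c, Z_c[:, s:s + block_size], y_center, ssy)
            for s in starts
        )
    r = np.concatenate([p[0] for p in parts])
    t = np.concatenate([p[1] for p in parts])
    p = np.concatenate([p[2] for p in parts])
    return ScreenResult(r=r, t=t, p=p, n_samples=n)


def select_candidates(scan: ScreenResult, threshold: float = DEFAULT_THRESHOLD) -> ScreenResult:
    """Retain markers with p strictly below the threshold.

    Returns a copy of the scan with ``selected``/``candidates`` filled in;
    an empty candidate set is a valid outcome.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    mask = scan.p < threshold
    return replace(
        scan,
        threshold=float(threshold),
        selected=mask,
        candidates=np.flatnonzero(mask),
    )
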