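"""In-memory container for an additive-coded genotype matrix."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenotypeMatrix"]


@dataclass
class GenotypeMatrix:
    """n x m matrix of additively coded marker genotypes.

    Rows are samples, columns are markers.  The coding convention is
    caller-defined (the simulator uses {-1, +1} for a two-homozygote panel
    or {-1, 0, +1} for Hardy-Weinberg three-class genotypes; VCF input is
    dosage-centered to {-1, 0, +1}).  ``positions`` are 1-based marker
    indices as reported in output tables.
    """

    matrix: np.ndarray
    marker_ids: np.ndarray = None
    positions: np.ndarray = None
    sample_ids: np.ndarray = None
    maf: np.ndarray | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise ValueError("genotype matrix must be 2-D (samples x markers)")
        n, m = self.matrix.shape
        if self.marker_ids is None:
            width = max(5, len(str(m)))
            self.marker_ids = np.array([f"M{i + 1:0{width}d}" for i in range(m)])
        else:
            self.marker_ids = np.asarray(self.marker_ids)
        if self.positions is None:
            self.positions = np.arange(1, m + 1, dtype=np.int64)
        else:
            self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.sample_ids is None:
            width = max(4, len(str(n)))
            self.sample_ids = np.array([f"S{i + 1:0{width}d}" for i in range(n)])
        else:
            self.sample_ids = np.asarray(self.sample_ids)
        if self.maf is not None:
            self.maf = np.asarray(self.maf, dtype=float)
        if len(self.marker_ids) != m or len(self.positions) != m:
            raise ValueError("marker metadata length does not match matrix")
        if len(self.sample_ids) != n:
            raise ValueError("sample metadata length does not match matrix")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_markers(self) -> int:
        return self.matrix.shape[1]

    def column_variances(self, ddof: int = 0) -> np.ndarray:
        return np.var(np.asarray(self.matrix, dtype=float), axis=0, ddof=ddof)

    def subset_markers(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            matrix=self.matrix[:, idx],
            marker_ids=self.marker_ids[idx],
            positions=self.positions[idx],
            sample_ids=self.sample_ids,
            maf=None if self.maf is None else self.maf[idx],
        )
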