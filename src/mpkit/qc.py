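"""Quality-control filters and log normalization for raw count matrices.

Two filters run on raw counts, in order: (1) drop genes detected
(count > 0) in at most ``min_cells_per_gene_exclusive`` cells; (2) drop
cells whose expressed-gene count lies strictly below the lower or strictly
above the upper percentile of the per-cell expressed-gene-count
distribution. After filtering, each cell is scaled to a common total
(counts-per-10K by default) and log(1 + x) transformed.

The percentile bounds are computed with linear interpolation on the
per-cell distribution, and cells exactly at a bound survive; when every
cell has the same expressed-gene count the distribution has zero width and
nothing is removed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .matrix import LOGNORM, RAW, ExpressionMatrix


class QCError(ValueError):
    pass


@dataclass
class QCConfig:
    #: genes detected in this many cells or fewer are removed
    min_cells_per_gene_exclusive: int = 5
    cell_gene_count_lower_pct: float = 2.0
    cell_gene_count_upper_pct: float = 98.0
    normalization_scale: float = 10_000.0

    def validate(self) -> None:
        if self.min_cells_per_gene_exclusive < 0:
            raise QCError("min_cells_per_gene_exclusive must be >= 0")
        if not (0 <= self.cell_gene_count_lower_pct < self.cell_gene_count_upper_pct <= 100):
            raise QCError("percentile bounds must satisfy 0 <= lower < upper <= 100")
        if self.normalization_scale <= 0:
            raise QCError("normalization_scale must be positive")


def _require_raw(m: ExpressionMatrix, op: str) -> None:
    if m.layer_state != RAW:
        raise QCError(f"{op} requires raw counts, matrix is {m.layer_state!r}")


def detection_counts(m: ExpressionMatrix) -> np.ndarray:
    """Number of cells in which each gene has a nonzero value."""
    return np.asarray((m.values > 0).sum(axis=1)).ravel()


def expressed_gene_counts(m: ExpressionMatrix) -> np.ndarray:
    """Number of genes with a nonzero value in each cell."""
    return np.asarray((m.values > 0).sum(axis=0)).ravel()


def filter_genes(m: ExpressionMatrix, qc: QCConfig) -> ExpressionMatrix:
    """Remove genes detected in ``min_cells_per_gene_exclusive`` or fewer cells."""
    qc.validate()
    _require_raw(m, "filter_genes")
    keep = detection_counts(m) > qc.min_cells_per_gene_exclusive
    if not keep.any():
        raise QCError("all genes filtered")
    return m.subset_genes(keep)


def filter_cells(m: ExpressionMatrix, qc: QCConfig) -> ExpressionMatrix:
    """Remove cells outside the configured expressed-gene-count percentiles."""
    qc.validate()
    _require_raw(m, "filter_cells")
    if m.n_cells < 3:
        raise QCError("fewer than 3 cells")
    counts = expressed_gene_counts(m)
    lo, hi = np.percentile(
        counts, [qc.cell_gene_count_lower_pct, qc.cell_gene_count_upper_pct]
    )
    keep = (counts >= lo) & (counts <= hi)
    return m.subset_cells(keep)


def lognormalize(m: ExpressionMatrix, scale: float = 10_000.0) -> ExpressionMatrix:
    """Scale each cell to ``scale`` total counts, then log(1 + x).

    Sparsity is preserved (zeros map to zero); a cell with zero total counts
    cannot be normalized and raises an error naming the offending cells.
    """
    _require_raw(m, "lognormalize")
    if scale <= 0:
        raise QCError("scale must be positive")
    totals = np.asarray(m.values.sum(axis=0)).ravel()
    zero = totals == 0
    if zero.any():
        ids = [m.cell_ids[i] for i in np.flatnonzero(zero)]
        raise QCError(f"cells with zero total counts: {ids}")
    X = m.values.tocsc().astype(float)
    X = X.multiply(scale / totals[None, :]).tocsr()
    X.data = np.log1p(X.data)
    return replace(m, values=X, layer_state=LOGNORM)


def run_qc(m: ExpressionMatrix, qc: QCConfig | None = None) -> ExpressionMatrix:
    """filter_genes → filter_cells → lognormalize, the standard order."""
    qc = qc or QCConfig()
    return lognormalize(filter_cells(filter_genes(m, qc), qc), qc.normalization_scale)
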