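"""Sparse gene-by-cell expression container shared by all pipeline stages.

The matrix is stored genes-as-rows (the 10x convention), values are raw
counts or log-normalized expression, and a per-cell annotation table rides
along with categorical labels (study, entity, cell_type, tissue, stage,
malignant) used by downstream grouping statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

RAW = "raw"
LOGNORM = "lognorm"

#: annotation columns the pipeline knows about; extra columns are allowed
STANDARD_ANNOTATIONS = ("study", "entity", "cell_type", "tissue", "stage", "malignant")


class MatrixValidationError(ValueError):
    """Raised when an ExpressionMatrix violates its structural invariants."""


@dataclass
class ExpressionMatrix:
    """A sparse non-negative gene×cell matrix with IDs and cell annotations.

    Parameters
    ----------
    values
        Sparse matrix of shape (n_genes, n_cells), non-negative.
    gene_ids, cell_ids
        Unique identifiers for rows and columns.
    annotations
        Per-cell table; the row order corresponds 1:1 with ``cell_ids``.
    layer_state
        ``"raw"`` for counts, ``"lognorm"`` after log normalization.
    """

    values: sp.spmatrix
    gene_ids: list[str]
    cell_ids: list[str]
    annotations: pd.DataFrame = field(default_factory=pd.DataFrame)
    layer_state: str = RAW

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise MatrixValidationError(
                f"gene_ids has {len(self.gene_ids)} entries for {n_genes} rows"
            )
        if len(self.cell_ids) != n_cells:
            raise MatrixValidationError(
                f"cell_ids has {len(self.cell_ids)} entries for {n_cells} columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise MatrixValidationError("duplicate gene IDs")
        if len(set(self.cell_ids)) != n_cells:
            raise MatrixValidationError("duplicate cell IDs")
        if self.values.nnz and self.values.data.min() < 0:
            raise MatrixValidationError("negative expression values")
        if self.annotations is None or len(self.annotations) == 0:
            self.annotations = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        else:
            if len(self.annotations) != n_cells:
                raise MatrixValidationError(
                    f"annotation table has {len(self.annotations)} rows for {n_cells} cells"
                )
            self.annotations = self.annotations.copy()
            self.annotations.index = pd.Index(self.cell_ids, name="cell_id")
        if self.layer_state not in (RAW, LOGNORM):
            raise MatrixValidationError(f"unknown layer_state {self.layer_state!r}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_genes(self, keep: np.ndarray) -> "ExpressionMatrix":
        """Row-subset by boolean mask or integer index, preserving order."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return replace(
            self,
            values=self.values[keep],
            gene_ids=[self.gene_ids[i] for i in keep],
            annotations=self.annotations,
        )

    def subset_cells(self, keep: np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return replace(
            self,
            values=self.values[:, keep],
            cell_ids=[self.cell_ids[i] for i in keep],
            annotations=self.annotations.iloc[keep],
        )

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())
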