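"""Labeled expression-matrix container shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp


@dataclass
class ExpressionDataset:
    """A cells x genes non-negative count matrix with per-cell type labels.

    Parameters
    ----------
    counts
        Dense ndarray or scipy sparse matrix, shape ``(n, m)``, cells in rows.
    cell_ids, gene_ids
        Row / column identifiers.
    labels
        Per-cell type names, length ``n``.
    """

    counts: np.ndarray | sp.spmatrix
    cell_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)
    labels: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))

    def __post_init__(self) -> None:
        if sp.issparse(self.counts):
            self.counts = sp.csr_matrix(self.counts)
        else:
            self.counts = np.asarray(self.counts)
        n, m = self.counts.shape
        if not self.cell_ids:
            self.cell_ids = [f"cell_{i}" for i in range(n)]
        if not self.gene_ids:
            self.gene_ids = [f"gene_{j}" for j in range(m)]
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} matrix rows")
        if len(self.gene_ids) != m:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {m} matrix columns")
        if self.labels.size and self.labels.size != n:
            raise ValueError(f"{self.labels.size} labels for {n} cells")
        if self.dense_counts().size and self.dense_counts().min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        """Number of cells."""
        return self.counts.shape[0]

    @property
    def m(self) -> int:
        """Number of genes."""
        return self.counts.shape[1]

    def dense_counts(self) -> np.ndarray:
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense())
        return self.counts

    def subset(self, cell_idx=None, gene_idx=None) -> "ExpressionDataset":
        """Row/column subset preserving order of the given indices."""
        cell_idx = np.arange(self.n) if cell_idx is None else np.asarray(cell_idx)
        gene_idx = np.arange(self.m) if gene_idx is None else np.asarray(gene_idx)
        counts = self.counts[cell_idx][:, gene_idx]
        return ExpressionDataset(
            counts=counts,
            cell_ids=[self.cell_ids[i] for i in cell_idx],
            gene_ids=[self.gene_ids[j] for j in gene_idx],
            labels=self.labels[cell_idx] if self.labels.size else self.labels,
        )
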