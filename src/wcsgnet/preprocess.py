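"""Filtering, CPM normalization, log views, HVG selection, up-sampling.

Two log views of the counts-per-million matrix are used downstream:

* ``E'`` with a small regularizer (epsilon = 1e-5) — node features for the
  classifier and the input to highly-variable-gene selection;
* ``E0`` with epsilon = 0, restricted to the selected genes — the input to
  network construction, where raw zeros must stay exactly zero so that the
  zero-expression edge rule applies cleanly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .datasets import ExpressionDataset

EPS_FEATURES = 1e-5

AMBIGUOUS_LABELS = {"", "unknown", "unclear", "nan", "na", "none", "ambiguous"}


def drop_ambiguous(ds: ExpressionDataset, extra: set[str] | None = None) -> ExpressionDataset:
    """Remove cells whose label is empty or in the ambiguous list."""
    bad = {s.lower() for s in AMBIGUOUS_LABELS | (extra or set())}
    keep = np.array(
        [lab is not None and str(lab).strip().lower() not in bad for lab in ds.labels]
    )
    return ds.subset(cell_idx=np.flatnonzero(keep))


def filter_dataset(
    ds: ExpressionDataset,
    min_cells_per_type: int = 10,
    min_cells_per_gene: int = 10,
) -> ExpressionDataset:
    """Drop small cell types, then genes expressed in too few surviving cells.

    The order matters: the type filter runs first, so a gene's expressing-cell
    count is taken over the cells that survive it.  Raises if either stage
    empties the dataset.
    """
    if ds.labels.size != ds.n:
        raise ValueError("filter_dataset requires per-cell labels")
    types, counts = np.unique(ds.labels, return_counts=True)
    keep_types = set(types[counts >= min_cells_per_type])
    cell_keep = np.flatnonzero([lab in keep_types for lab in ds.labels])
    if cell_keep.size == 0:
        raise ValueError(
            f"cell-type filter (min {min_cells_per_type} cells/type) removed all cells"
        )
    ds = ds.subset(cell_idx=cell_keep)

    X = ds.dense_counts()
    expressed_in = (X > 0).sum(axis=0)
    gene_keep = np.flatnonzero(expressed_in >= min_cells_per_gene)
    if gene_keep.size == 0:
        raise ValueError(
            f"gene filter (expressed in >= {min_cells_per_gene} cells) removed all genes"
        )
    return ds.subset(gene_idx=gene_keep)


def cpm_normalize(ds: ExpressionDataset) -> np.ndarray:
    """Counts-per-million: each row scaled to total 1e6."""
    X = ds.dense_counts().astype(np.float64)
    totals = X.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        ids = [ds.cell_ids[i] for i in zero[:10]]
        raise ValueError(f"cells with zero total count cannot be CPM-normalized: {ids}")
    return X / totals[:, None] * 1e6


def log_transform(E: np.ndarray, epsilon: float) -> np.ndarray:
    """Elementwise ln(e + epsilon + 1)."""
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    E = np.asarray(E, dtype=np.float64)
    if E.size and E.min() < 0:
        raise ValueError("expression values must be non-negative")
    return np.log(E + epsilon + 1.0)


def select_hvgs(
    E_prime: np.ndarray,
    gene_ids: list[str],
    p: int = 2000,
    n_bins: int | None = None,
) -> list[str]:
    """Top-``p`` highly variable genes by expression dispersion.

    Genes are mapped back to the linear scale (expm1 of the log view) and
    ranked by dispersion = variance/mean, ties broken by input order.  With
    ``n_bins`` set, the dispersion is instead z-scored within quantile bins
    of comparable mean expression (the Seurat-style variant) before ranking.
    The unbinned criterion is the default: on small gene panels where the
    informative genes dominate the high-expression bins, within-bin
    normalization cancels exactly the variability it is meant to find.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    E_prime = np.asarray(E_prime, dtype=np.float64)
    m = E_prime.shape[1]
    if len(gene_ids) != m:
        raise ValueError("gene_ids length does not match matrix columns")

    X = np.expm1(E_prime)
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(m)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)

    if n_bins is None:
        rank = np.lexsort((np.arange(m), -disp))
        return [gene_ids[j] for j in rank[: min(p, m)]]

    n_bins_eff = min(n_bins, m)
    # quantile bins on the mean so each bin holds comparable-abundance genes
    order = np.argsort(mean, kind="stable")
    bin_of = np.empty(m, dtype=np.int64)
    bin_of[order] = np.minimum((np.arange(m) * n_bins_eff) // m, n_bins_eff - 1)

    disp_norm = np.zeros(m)
    for b in np.unique(bin_of):
        members = np.flatnonzero(bin_of == b)
        d = disp[members]
        center = np.median(d)
        spread = d.std(ddof=1) if members.size > 1 else 0.0
        if spread > 0:
            disp_norm[members] = (d - center) / spread
        else:
            disp_norm[members] = d - center

    rank = np.lexsort((np.arange(m), -disp, -disp_norm))
    return [gene_ids[j] for j in rank[: min(p, m)]]


@dataclass
class ProcessedViews:
    """The two log views plus the selected gene list."""

    E_prime_expr: np.ndarray  # n x p, epsilon=1e-5 log view over HVGs
    E0_wcsn: np.ndarray  # n x p, epsilon=0 log view over HVGs
    hvg_ids: list[str]

    @property
    def p(self) -> int:
        return len(self.hvg_ids)


def make_views(
    ds: ExpressionDataset,
    hvg_ids: list[str] | None = None,
    p: int = 2000,
) -> ProcessedViews:
    """CPM-normalize and produce both log views restricted to the HVG list.

    When ``hvg_ids`` is given (e.g. a list selected on training cells only)
    it is used verbatim; otherwise selection runs on this dataset.
    """
    E = cpm_normalize(ds)
    if hvg_ids is None:
        E_prime_full = log_transform(E, EPS_FEATURES)
        hvg_ids = select_hvgs(E_prime_full, ds.gene_ids, p=p)
    col = {g: j for j, g in enumerate(ds.gene_ids)}
    idx = np.array([col[g] for g in hvg_ids])
    E_hvg = E[:, idx]
    return ProcessedViews(
        E_prime_expr=log_transform(E_hvg, EPS_FEATURES),
        E0_wcsn=log_transform(E_hvg, 0.0),
        hvg_ids=list(hvg_ids),
    )


def upsample_training(
    labels: np.ndarray,
    train_indices: np.ndarray,
    min_frac: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Balance a training fold by duplicating cells of under-sized types.

    Any type whose training size is below ``min_frac`` of the largest type's
    is topped up to ``ceil(min_frac * s_max)`` by sampling its own cells with
    replacement.  Original indices are always retained; other types are
    untouched; test cells are never involved.
    """
    train_indices = np.asarray(train_indices)
    if train_indices.size == 0:
        raise ValueError("train_indices must be non-empty")
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must lie in (0, 1]")
    labels = np.asarray(labels, dtype=object)
    rng = np.random.default_rng(seed)
    train_labels = labels[train_indices]
    types, counts = np.unique(train_labels, return_counts=True)
    s_max = counts.max()
    target = math.ceil(min_frac * s_max)
    out = [train_indices]
    for t, s in zip(types, counts):
        if s < min_frac * s_max:
            pool = train_indices[train_labels == t]
            out.append(rng.choice(pool, size=target - s, replace=True))
    return np.concatenate(out)
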