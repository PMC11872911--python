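"""Readers/writers for expression data, networks and run manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datasets import ExpressionDataset
from .wcsn import CellNetwork


def derive_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed from a single global seed via stable hashing."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()


# ---- expression matrices -------------------------------------------------


def write_mtx(ds: ExpressionDataset, outdir: str | Path) -> None:
    """MTX triplet: matrix.mtx (cells x genes), cells.tsv (id, label), genes.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), sp.csr_matrix(ds.dense_counts()))
    labels = ds.labels if ds.labels.size else [""] * ds.n
    pd.DataFrame({"cell_id": ds.cell_ids, "label": labels}).to_csv(
        outdir / "cells.tsv", sep="\t", index=False
    )
    pd.DataFrame({"gene_id": ds.gene_ids}).to_csv(
        outdir / "genes.tsv", sep="\t", index=False
    )


def _read_mtx(path: Path) -> ExpressionDataset:
    counts = sp.csr_matrix(scipy.io.mmread(str(path / "matrix.mtx")))
    cells_f = path / "cells.tsv"
    genes_f = path / "genes.tsv"
    if not cells_f.exists():
        raise FileNotFoundError(f"missing labels file {cells_f}")
    cells = pd.read_csv(cells_f, sep="\t")
    genes = pd.read_csv(genes_f, sep="\t")
    if counts.shape[0] != len(cells):
        if counts.shape[1] == len(cells):
            counts = counts.T.tocsr()
        else:
            raise ValueError(
                f"{path / 'matrix.mtx'}: {counts.shape} incompatible with "
                f"{len(cells)} cells / {len(genes)} genes"
            )
    if counts.shape[1] != len(genes):
        raise ValueError(f"{genes_f}: {len(genes)} genes for matrix {counts.shape}")
    return ExpressionDataset(
        counts=counts,
        cell_ids=cells.iloc[:, 0].astype(str).tolist(),
        gene_ids=genes.iloc[:, 0].astype(str).tolist(),
        labels=cells["label"].to_numpy() if "label" in cells else np.array([]),
    )


def _read_csv(path: Path, labels_path: Path | None, transpose: bool) -> ExpressionDataset:
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if transpose:
        df = df.T
    labels = np.array([])
    if labels_path is not None:
        lab = pd.read_csv(labels_path, sep="\t", index_col=0)
        missing = [c for c in df.index if c not in lab.index]
        if missing:
            raise ValueError(
                f"{labels_path}: no label for cells {missing[:5]} "
                "(is the matrix orientation right? try --transpose)"
            )
        labels = lab.loc[df.index].iloc[:, 0].to_numpy()
    return ExpressionDataset(
        counts=df.to_numpy(),
        cell_ids=df.index.astype(str).tolist(),
        gene_ids=df.columns.astype(str).tolist(),
        labels=labels,
    )


def _read_h5ad(path: Path) -> ExpressionDataset:
    import anndata

    ad = anndata.read_h5ad(path)
    label_col = next(
        (c for c in ("cell_type", "label", "labels") if c in ad.obs), None
    )
    if label_col is None:
        raise ValueError(f"{path}: no cell_type/label column in .obs")
    return ExpressionDataset(
        counts=ad.X if not sp.issparse(ad.X) else sp.csr_matrix(ad.X),
        cell_ids=ad.obs_names.tolist(),
        gene_ids=ad.var_names.tolist(),
        labels=ad.obs[label_col].to_numpy(),
    )


def write_h5ad(ds: ExpressionDataset, path: str | Path) -> None:
    import anndata
    import pandas as pd

    ad = anndata.AnnData(
        X=sp.csr_matrix(ds.dense_counts()),
        obs=pd.DataFrame({"cell_type": ds.labels}, index=ds.cell_ids),
        var=pd.DataFrame(index=ds.gene_ids),
    )
    ad.write_h5ad(path)


def load_expression(
    path: str | Path,
    fmt: str = "auto",
    labels: str | Path | None = None,
    transpose: bool = False,
) -> ExpressionDataset:
    """Load a labeled cells x genes count matrix from MTX/CSV/h5ad."""
    path = Path(path)
    if fmt == "auto":
        if path.is_dir():
            fmt = "mtx"
        elif path.suffix == ".h5ad":
            fmt = "h5ad"
        elif path.suffix in (".csv", ".tsv", ".txt"):
            fmt = "csv"
        else:
            raise ValueError(f"cannot infer format of {path}")
    if fmt == "mtx":
        return _read_mtx(path)
    if fmt == "csv":
        return _read_csv(path, Path(labels) if labels else None, transpose)
    if fmt == "h5ad":
        return _read_h5ad(path)
    raise ValueError(f"unknown format {fmt!r}")


# ---- networks ------------------------------------------------------------


def write_networks_tsv(networks: list[CellNetwork], gene_ids, cell_ids, path) -> None:
    rows = []
    for net, cid in zip(networks, cell_ids):
        for u, v, w in zip(net.u, net.v, net.weight):
            rows.append((cid, gene_ids[u], gene_ids[v], w))
    pd.DataFrame(rows, columns=["cell_id", "gene_u", "gene_v", "weight"]).to_csv(
        path, sep="\t", index=False
    )


# ---- manifests -----------------------------------------------------------


def write_manifest(path: str | Path, cfg: dict, seed: int) -> None:
    manifest = {"config": cfg, "seed": seed, "config_hash": config_hash(cfg)}
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))


def verify_manifest(path: str | Path) -> bool:
    manifest = json.loads(Path(path).read_text())
    return manifest.get("config_hash") == config_hash(manifest.get("config", {}))
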