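"""Topology analysis of per-cell networks: hubs, high-weight edges,
cross-fold coverage, characteristic sets, uniqueness.

For every cell type and cross-validation fold, genes are ranked by their
average degree over the type's test-fold networks and edges by their average
weight (a cell lacking an edge contributes 0 to that edge's mean).  The
top-k lists feed three summary statistics: coverage (fraction of the top-k
list shared by all five folds), the characteristic set (union of the five
top-k lists), and uniqueness (fraction of a type's characteristic set found
in no other type's characteristic set).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .wcsn import CellNetwork


@dataclass
class TypeFoldSummary:
    cell_type: str
    fold_id: int
    mean_degree: np.ndarray  # per-gene, length p
    mean_edge_weight: dict  # (u, v) -> mean weight over the type's cells
    top_hub_genes: list[int]
    top_edges: list[tuple[int, int]]


@dataclass
class CharacteristicSet:
    cell_type: str
    elements: set
    coverage: float
    uniqueness: float | None = None


def summarize_type_fold(
    networks: list[CellNetwork], k: int = 100, cell_type: str = "", fold_id: int = 0
) -> TypeFoldSummary:
    """Rank hubs and edges for one type in one fold.

    Mean degree is the unweighted degree averaged over the given cells; mean
    edge weight averages over all given cells with absent edges counting 0.
    Top lists are descending by mean, ties by ascending gene (or pair) index,
    truncated to the number of items that ever appear.
    """
    if not networks:
        raise ValueError("summarize_type_fold needs at least one network")
    p = networks[0].p
    n_cells = len(networks)
    degree = np.zeros(p)
    weight_sums: dict[tuple[int, int], float] = defaultdict(float)
    for net in networks:
        np.add.at(degree, net.u, 1)
        np.add.at(degree, net.v, 1)
        for u, v, w in zip(net.u.tolist(), net.v.tolist(), net.weight.tolist()):
            weight_sums[(u, v)] += w
    mean_degree = degree / n_cells
    mean_weight = {e: s / n_cells for e, s in weight_sums.items()}

    connected = np.flatnonzero(mean_degree > 0)
    hub_order = sorted(connected.tolist(), key=lambda g: (-mean_degree[g], g))
    edge_order = sorted(mean_weight, key=lambda e: (-mean_weight[e], e))
    return TypeFoldSummary(
        cell_type=cell_type,
        fold_id=fold_id,
        mean_degree=mean_degree,
        mean_edge_weight=mean_weight,
        top_hub_genes=hub_order[:k],
        top_edges=edge_order[:k],
    )


def coverage(per_fold_top_lists: list, k: int) -> float:
    """|intersection of the five folds' top-k sets| / k."""
    if len(per_fold_top_lists) != 5:
        raise ValueError(f"coverage is defined over 5 folds, got {len(per_fold_top_lists)}")
    sets = [set(s) for s in per_fold_top_lists]
    if any(len(s) > k for s in sets):
        raise ValueError("a fold's top list exceeds k elements")
    return len(set.intersection(*sets)) / k


def characteristic_set(per_fold_top_lists: list) -> set:
    """Union of the folds' top-k sets: the type's characteristic elements."""
    return set().union(*(set(s) for s in per_fold_top_lists))


def uniqueness(sets_by_type: dict) -> dict:
    """Per type: fraction of its characteristic set found in no other type's.

    Undefined (raises) for fewer than two types.
    """
    if len(sets_by_type) < 2:
        raise ValueError("uniqueness requires at least two cell types")
    out = {}
    for t, elems in sets_by_type.items():
        elems = set(elems)
        others = set().union(
            *(set(e) for u, e in sets_by_type.items() if u != t)
        )
        out[t] = len(elems - others) / len(elems) if elems else 0.0
    return out


def analyze_types(
    networks_by_type_fold: dict,
    k: int = 100,
) -> tuple[dict, dict]:
    """End-to-end topology summary from {type: {fold: [networks]}}.

    Returns (gene_sets, edge_sets): each maps type -> CharacteristicSet with
    coverage and uniqueness filled in.
    """
    hub_lists: dict[str, list] = {}
    edge_lists: dict[str, list] = {}
    for t, folds in networks_by_type_fold.items():
        hub_lists[t] = []
        edge_lists[t] = []
        for fold_id in sorted(folds):
            s = summarize_type_fold(folds[fold_id], k=k, cell_type=t, fold_id=fold_id)
            hub_lists[t].append(s.top_hub_genes)
            edge_lists[t].append(s.top_edges)

    def build(lists_by_type):
        sets = {t: characteristic_set(ls) for t, ls in lists_by_type.items()}
        uniq = uniqueness(sets) if len(sets) > 1 else {t: None for t in sets}
        return {
            t: CharacteristicSet(
                cell_type=t,
                elements=sets[t],
                coverage=coverage(lists_by_type[t], k),
                uniqueness=uniq[t],
            )
            for t in sets
        }

    return build(hub_lists), build(edge_lists)
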