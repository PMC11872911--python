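"""Weighted cell-specific network (WCSN) construction.

For one cell k and a gene pair (u, v), draw a neighborhood window around the
cell's expression value of each gene — the 0.1*n cells nearest in value —
and compare the joint window occupancy against the product of the marginals.
Under independence the deviation

    rho'_k(u,v) = sqrt(n-1) * (n*n_uv - n_u*n_v)
                  / sqrt(n_u*n_v*(n-n_u)*(n-n_v))

is approximately standard normal, so a one-sided z-test at level alpha
(default 0.01) decides whether the pair is associated in this cell; the
statistic itself becomes the edge weight.  A gene with zero expression in
cell k forms no edges in cell k's network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import norm


@dataclass
class WcsnConfig:
    """Window fraction, test level and edge-weight representation."""

    box_fraction: float = 0.1
    alpha: float = 0.01
    weight_mode: str = "raw"  # raw | log1p | binary

    def __post_init__(self) -> None:
        if not 0 < self.box_fraction < 1:
            raise ValueError("box_fraction must lie in (0, 1)")
        if not 0 < self.alpha < 0.5:
            raise ValueError("alpha must lie in (0, 0.5)")
        if self.weight_mode not in ("raw", "log1p", "binary"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")


@dataclass
class PairStatistic:
    """The count/frequency bundle of one gene pair in one cell."""

    n: int
    n_u: int
    n_v: int
    n_uv: int
    rho: float
    sigma: float
    rho_norm: float


@dataclass
class CellNetwork:
    """One cell's undirected weighted gene graph over the p HVG nodes.

    Edges are stored once with ``u < v``; ``weight_mode`` records which
    representation the weights carry.
    """

    cell_index: int
    u: np.ndarray
    v: np.ndarray
    weight: np.ndarray
    p: int
    weight_mode: str = "raw"

    @property
    def edges(self) -> list[tuple[int, int, float]]:
        return list(zip(self.u.tolist(), self.v.tolist(), self.weight.tolist()))

    @property
    def n_edges(self) -> int:
        return int(self.u.size)


def window_size(n: int, box_fraction: float) -> int:
    """Number of window members: max(1, round(box_fraction * n))."""
    return max(1, round(box_fraction * n))


def window_members(values: np.ndarray, k: int, box_fraction: float) -> np.ndarray:
    """Indices of the m cells whose values are nearest ``values[k]``.

    m = max(1, round(box_fraction*n)); ties in distance break by ascending
    cell index, so the result is deterministic.  The anchor cell itself is
    always a member (distance zero).
    """
    values = np.asarray(values, dtype=np.float64)
    n = values.size
    if n < 10:
        raise ValueError(f"n = {n} is too small for a {box_fraction} window")
    if values[k] <= 0:
        raise ValueError("window is undefined for a zero-expression anchor")
    m = window_size(n, box_fraction)
    dist = np.abs(values - values[k])
    order = np.lexsort((np.arange(n), dist))
    return np.sort(order[:m])


def pair_statistic(n: int, n_u: int, n_v: int, n_uv: int) -> PairStatistic:
    """Compute rho, sigma and the normalized statistic from window counts."""
    if not (0 < n_u < n and 0 < n_v < n):
        raise ValueError("window counts must satisfy 0 < n_u, n_v < n (sigma > 0)")
    if not 0 <= n_uv <= min(n_u, n_v):
        raise ValueError("joint count must satisfy 0 <= n_uv <= min(n_u, n_v)")
    rho = n_uv / n - (n_u / n) * (n_v / n)
    sigma = math.sqrt(n_u * n_v * (n - n_u) * (n - n_v) / (n**4 * (n - 1)))
    rho_norm = (
        math.sqrt(n - 1)
        * (n * n_uv - n_u * n_v)
        / math.sqrt(n_u * n_v * (n - n_u) * (n - n_v))
    )
    return PairStatistic(n=n, n_u=n_u, n_v=n_v, n_uv=n_uv, rho=rho, sigma=sigma, rho_norm=rho_norm)


def critical_value(alpha: float) -> float:
    """Upper-tail standard-normal quantile z with P(Z > z) = alpha."""
    if not 0 < alpha <= 0.5:
        raise ValueError("alpha must lie in (0, 0.5]")
    return float(norm.isf(alpha))


def _network_for_anchor(E0: np.ndarray, k: int, cfg: WcsnConfig) -> CellNetwork:
    """Vectorized single-anchor construction over all active gene pairs.

    For every gene with positive expression in cell k, window membership over
    the n pool cells is found by a stable sort on |value - anchor| (ties by
    index), giving a boolean membership matrix B (n x p_active).  Joint window
    counts for all pairs are then B^T B in one matmul, and because every
    window holds exactly m members the statistic reduces to
    sqrt(n-1)*(n*J - m^2)/(m*(n-m)).
    """
    n, p = E0.shape
    m = window_size(n, cfg.box_fraction)
    if not 0 < m < n:
        raise ValueError(f"degenerate window: m={m} of n={n}")
    active = np.flatnonzero(E0[k] > 0)
    if active.size < 2:
        return CellNetwork(
            cell_index=k,
            u=np.empty(0, dtype=np.int64),
            v=np.empty(0, dtype=np.int64),
            weight=np.empty(0, dtype=np.float64),
            p=p,
            weight_mode="raw",
        )
    sub = E0[:, active]
    dist = np.abs(sub - sub[k][None, :])  # n x p_active
    order = np.argsort(dist, axis=0, kind="stable")[:m]  # m x p_active
    B = np.zeros((n, active.size), dtype=np.float64)
    B[order, np.arange(active.size)[None, :]] = 1.0
    J = B.T @ B  # joint window counts, p_active x p_active
    rho_norm = math.sqrt(n - 1) * (n * J - m * m) / (m * (n - m))
    z = critical_value(cfg.alpha)
    iu, iv = np.triu_indices(active.size, k=1)
    keep = rho_norm[iu, iv] > z
    net = CellNetwork(
        cell_index=k,
        u=active[iu[keep]],
        v=active[iv[keep]],
        weight=rho_norm[iu, iv][keep].astype(np.float64),
        p=p,
        weight_mode="raw",
    )
    if cfg.weight_mode != "raw":
        net = transform_weights(net, cfg.weight_mode)
    return net


def build_cell_network(E0: np.ndarray, k: int, cfg: WcsnConfig | None = None) -> CellNetwork:
    """Build cell k's network with the statistic pool = all rows of E0."""
    cfg = cfg or WcsnConfig()
    E0 = np.asarray(E0, dtype=np.float64)
    n = E0.shape[0]
    if not 0 <= k < n:
        raise IndexError(f"cell index {k} out of range for {n} cells")
    return _network_for_anchor(E0, k, cfg)


def build_training_networks(
    E0_train: np.ndarray, cfg: WcsnConfig | None = None
) -> list[CellNetwork]:
    """One network per training cell, pool = training cells only.

    No information from any test cell enters these networks; they are
    identical whether or not test data exists.
    """
    cfg = cfg or WcsnConfig()
    E0_train = np.asarray(E0_train, dtype=np.float64)
    return [_network_for_anchor(E0_train, k, cfg) for k in range(E0_train.shape[0])]


def build_test_network(
    E0_train: np.ndarray, x_test: np.ndarray, cfg: WcsnConfig | None = None
) -> CellNetwork:
    """Network of a single held-out cell, pool = training cells + this cell.

    The test cell is appended to the training pool individually, so the pool
    size is n_train + 1 and no test cell ever influences another test cell's
    network or any training network.
    """
    cfg = cfg or WcsnConfig()
    E0_train = np.asarray(E0_train, dtype=np.float64)
    x_test = np.asarray(x_test, dtype=np.float64).ravel()
    if x_test.size != E0_train.shape[1]:
        raise ValueError(
            f"test cell has {x_test.size} genes, training pool has {E0_train.shape[1]}"
        )
    pool = np.vstack([E0_train, x_test[None, :]])
    net = _network_for_anchor(pool, pool.shape[0] - 1, cfg)
    return replace(net, cell_index=-1)


def transform_weights(net: CellNetwork, mode: str) -> CellNetwork:
    """Re-represent edge weights: raw (identity), log1p, or binary.

    The log transform ln(w+1) compresses the heavy right tail of the raw
    statistics; the binary transform keeps topology only.  The edge set is
    unchanged in every mode.
    """
    if net.weight_mode != "raw":
        raise ValueError("transform_weights expects a raw-mode network")
    if mode == "raw":
        return net
    if mode == "log1p":
        return replace(net, weight=np.log1p(net.weight), weight_mode="log1p")
    if mode == "binary":
        return replace(net, weight=np.ones_like(net.weight), weight_mode="binary")
    raise ValueError(f"unknown weight mode {mode!r}")
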