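"""Numpy implementation of the graph-convolution classifier network.

Architecture, applied to one cell's gene graph (p nodes, scalar expression
features):

    graph conv (1 -> 16)        h'(v) = A1 h(v) + A2 sum_{j in N(v)} w_v(j) h(j) + b
    LayerNorm(16) per node, ReLU
    per-gene channel mixing 16 -> 12 (1x1 conv), ReLU, BatchNorm, Dropout
    per-gene channel mixing 12 -> 4  (1x1 conv), ReLU, BatchNorm, Dropout
    flatten (channels-first, 4*p) -> FC 256 -> ReLU -> FC 64 -> ReLU -> FC c

All forward and backward passes are written out explicitly; gradients are
verified against numerical differentiation in the test suite.  Message
passing uses one block-diagonal sparse adjacency per minibatch, so a batch
of graphs is a single sparse-dense product.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

_BN_EPS = 1e-5
_LN_EPS = 1e-5
_BN_MOMENTUM = 0.1


def kaiming_normal(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """He-normal init: N(0, sqrt(2/fan_in)), fan_in = shape[1]."""
    return rng.normal(0.0, np.sqrt(2.0 / shape[1]), size=shape)


def graph_conv(
    features: np.ndarray,
    edges: np.ndarray,
    edge_weights: np.ndarray,
    A1: np.ndarray,
    A2: np.ndarray,
    bias: np.ndarray | None = None,
) -> np.ndarray:
    """Single weighted graph-convolution layer on one graph.

    ``features`` is (p, d_in); ``edges`` is (E, 2) of directed (target,
    source) pairs — an undirected edge appears once in each direction —
    and ``edge_weights`` its weights.  Returns (p, d_out).
    """
    features = np.asarray(features, dtype=np.float64)
    p = features.shape[0]
    if A1.shape != A2.shape or A1.shape[1] != features.shape[1]:
        raise ValueError("A1/A2 shapes incompatible with features")
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    w = np.asarray(edge_weights, dtype=np.float64).ravel()
    if edges.shape[0] != w.size:
        raise ValueError("edges and edge_weights length mismatch")
    agg = np.zeros_like(features)
    if edges.size:
        if edges.max() >= p:
            raise ValueError("edge endpoint out of range")
        np.add.at(agg, edges[:, 0], w[:, None] * features[edges[:, 1]])
    out = features @ A1.T + agg @ A2.T
    if bias is not None:
        out = out + bias
    return out


class GraphConvNet:
    """The full classifier network with explicit forward/backward."""

    def __init__(
        self,
        p: int,
        n_classes: int,
        embed_dim: int = 16,
        conv_channels: tuple[int, int] = (12, 4),
        mlp_hidden: tuple[int, int] = (256, 64),
        dropout: float = 0.3,
        seed: int = 0,
    ) -> None:
        self.p = p
        self.n_classes = n_classes
        self.embed_dim = embed_dim
        self.conv_channels = tuple(conv_channels)
        self.mlp_hidden = tuple(mlp_hidden)
        self.dropout = dropout
        self.bn_momentum = _BN_MOMENTUM
        rng = np.random.default_rng(seed)
        c1, c2 = self.conv_channels
        h1, h2 = self.mlp_hidden
        d = embed_dim
        self.params: dict[str, np.ndarray] = {
            "gc_A1": kaiming_normal(rng, (d, 1)),
            "gc_A2": kaiming_normal(rng, (d, 1)),
            "gc_b": np.zeros(d),
            "ln_g": np.ones(d),
            "ln_b": np.zeros(d),
            "c1_W": kaiming_normal(rng, (c1, d)),
            "c1_b": np.zeros(c1),
            "bn1_g": np.ones(c1),
            "bn1_b": np.zeros(c1),
            "c2_W": kaiming_normal(rng, (c2, c1)),
            "c2_b": np.zeros(c2),
            "bn2_g": np.ones(c2),
            "bn2_b": np.zeros(c2),
            "fc1_W": kaiming_normal(rng, (h1, c2 * p)),
            "fc1_b": np.zeros(h1),
            "fc2_W": kaiming_normal(rng, (h2, h1)),
            "fc2_b": np.zeros(h2),
            "fc3_W": kaiming_normal(rng, (n_classes, h2)),
            "fc3_b": np.zeros(n_classes),
        }
        self.running: dict[str, np.ndarray] = {
            "bn1_mean": np.zeros(c1),
            "bn1_var": np.ones(c1),
            "bn2_mean": np.zeros(c2),
            "bn2_var": np.ones(c2),
        }

    # ---- forward -------------------------------------------------------

    def forward(
        self,
        X: np.ndarray,
        A: sp.spmatrix,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, dict]:
        """Run a minibatch; returns (logits (B, c), cache for backward).

        ``X`` is (B, p) node scalar features; ``A`` the (B*p, B*p)
        block-diagonal weighted adjacency of the batch.
        """
        P = self.params
        B, p = X.shape
        if p != self.p:
            raise ValueError(f"expected {self.p} nodes per graph, got {p}")
        H0 = X.reshape(B * p, 1)
        agg = A @ H0
        H1 = H0 @ P["gc_A1"].T + agg @ P["gc_A2"].T + P["gc_b"]

        mu = H1.mean(axis=1, keepdims=True)
        var = H1.var(axis=1, keepdims=True)
        inv = 1.0 / np.sqrt(var + _LN_EPS)
        xhat = (H1 - mu) * inv
        H2 = P["ln_g"] * xhat + P["ln_b"]
        H3 = np.maximum(H2, 0.0)

        Z1 = H3 @ P["c1_W"].T + P["c1_b"]
        R1 = np.maximum(Z1, 0.0)
        N1, bn1 = self._bn_forward(R1, "bn1", training)
        D1, m1 = self._dropout(N1, training, rng)

        Z2 = D1 @ P["c2_W"].T + P["c2_b"]
        R2 = np.maximum(Z2, 0.0)
        N2, bn2 = self._bn_forward(R2, "bn2", training)
        D2, m2 = self._dropout(N2, training, rng)

        c2 = self.conv_channels[1]
        F = D2.reshape(B, p, c2).transpose(0, 2, 1).reshape(B, c2 * p)
        G1 = F @ P["fc1_W"].T + P["fc1_b"]
        G1r = np.maximum(G1, 0.0)
        G2 = G1r @ P["fc2_W"].T + P["fc2_b"]
        G2r = np.maximum(G2, 0.0)
        logits = G2r @ P["fc3_W"].T + P["fc3_b"]

        cache = dict(
            A=A, B=B, H0=H0, agg=agg, H1=H1, mu=mu, inv=inv, xhat=xhat, H2=H2,
            H3=H3, Z1=Z1, R1=R1, bn1=bn1, m1=m1, D1=D1, Z2=Z2, R2=R2, bn2=bn2,
            m2=m2, D2=D2, F=F, G1=G1, G1r=G1r, G2=G2, G2r=G2r,
        )
        return logits, cache

    def _bn_forward(self, x: np.ndarray, name: str, training: bool):
        P = self.params
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            R = self.running
            mom = self.bn_momentum
            R[f"{name}_mean"] = (1 - mom) * R[f"{name}_mean"] + mom * mean
            nb = x.shape[0]
            unbiased = var * nb / max(nb - 1, 1)
            R[f"{name}_var"] = (1 - mom) * R[f"{name}_var"] + mom * unbiased
        else:
            mean = self.running[f"{name}_mean"]
            var = self.running[f"{name}_var"]
        inv = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (x - mean) * inv
        out = P[f"{name}_g"] * xhat + P[f"{name}_b"]
        return out, dict(xhat=xhat, inv=inv, training=training)

    def _dropout(self, x: np.ndarray, training: bool, rng):
        if not training or self.dropout <= 0:
            return x, None
        if rng is None:
            raise ValueError("training-mode forward needs an rng for dropout")
        mask = (rng.random(x.shape) >= self.dropout) / (1.0 - self.dropout)
        return x * mask, mask

    # ---- backward ------------------------------------------------------

    def backward(self, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of the scalar loss wrt every parameter."""
        P = self.params
        g: dict[str, np.ndarray] = {}
        B = cache["B"]
        p = self.p
        c2 = self.conv_channels[1]

        g["fc3_W"] = dlogits.T @ cache["G2r"]
        g["fc3_b"] = dlogits.sum(axis=0)
        dG2r = dlogits @ P["fc3_W"]
        dG2 = dG2r * (cache["G2"] > 0)
        g["fc2_W"] = dG2.T @ cache["G1r"]
        g["fc2_b"] = dG2.sum(axis=0)
        dG1r = dG2 @ P["fc2_W"]
        dG1 = dG1r * (cache["G1"] > 0)
        g["fc1_W"] = dG1.T @ cache["F"]
        g["fc1_b"] = dG1.sum(axis=0)
        dF = dG1 @ P["fc1_W"]
        dD2 = dF.reshape(B, c2, p).transpose(0, 2, 1).reshape(B * p, c2)

        if cache["m2"] is not None:
            dD2 = dD2 * cache["m2"]
        dR2, dg2, db2 = self._bn_backward(dD2, cache["bn2"], "bn2")
        g["bn2_g"], g["bn2_b"] = dg2, db2
        dZ2 = dR2 * (cache["Z2"] > 0)
        g["c2_W"] = dZ2.T @ cache["D1"]
        g["c2_b"] = dZ2.sum(axis=0)
        dD1 = dZ2 @ P["c2_W"]

        if cache["m1"] is not None:
            dD1 = dD1 * cache["m1"]
        dR1, dg1, db1 = self._bn_backward(dD1, cache["bn1"], "bn1")
        g["bn1_g"], g["bn1_b"] = dg1, db1
        dZ1 = dR1 * (cache["Z1"] > 0)
        g["c1_W"] = dZ1.T @ cache["H3"]
        g["c1_b"] = dZ1.sum(axis=0)
        dH3 = dZ1 @ P["c1_W"]

        dH2 = dH3 * (cache["H2"] > 0)
        g["ln_g"] = (dH2 * cache["xhat"]).sum(axis=0)
        g["ln_b"] = dH2.sum(axis=0)
        dxhat = dH2 * P["ln_g"]
        # LayerNorm backward, per row over the d features
        d = cache["xhat"].shape[1]
        inv = cache["inv"]
        xhat = cache["xhat"]
        dH1 = (inv / d) * (
            d * dxhat
            - dxhat.sum(axis=1, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=1, keepdims=True)
        )

        g["gc_b"] = dH1.sum(axis=0)
        g["gc_A1"] = dH1.T @ cache["H0"]
        g["gc_A2"] = dH1.T @ cache["agg"]
        return g

    def _bn_backward(self, dout: np.ndarray, bn: dict, name: str):
        P = self.params
        dgamma = (dout * bn["xhat"]).sum(axis=0)
        dbeta = dout.sum(axis=0)
        dxhat = dout * P[f"{name}_g"]
        if not bn["training"]:
            return dxhat * bn["inv"], dgamma, dbeta
        nb = dout.shape[0]
        xhat = bn["xhat"]
        dx = (bn["inv"] / nb) * (
            nb * dxhat
            - dxhat.sum(axis=0)
            - xhat * (dxhat * xhat).sum(axis=0)
        )
        return dx, dgamma, dbeta

    def state_dict(self) -> dict:
        return {
            "params": {k: v.copy() for k, v in self.params.items()},
            "running": {k: v.copy() for k, v in self.running.items()},
        }

    def load_state_dict(self, state: dict) -> None:
        for k, v in state["params"].items():
            self.params[k] = np.asarray(v, dtype=np.float64)
        for k, v in state["running"].items():
            self.running[k] = np.asarray(v, dtype=np.float64)


class Adam:
    """Adam with additive L2 weight decay and a per-epoch exponential lr."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 0.01,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 1e-4,
    ) -> None:
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(
        self,
        grads: dict[str, np.ndarray],
        lr: float | None = None,
        clip_norm: float | None = None,
    ) -> None:
        lr = self.lr if lr is None else lr
        if clip_norm is not None:
            total = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
            if total > clip_norm:
                scale = clip_norm / total
                grads = {k: g * scale for k, g in grads.items()}
        b1, b2 = self.betas
        self.t += 1
        for k, param in self.params.items():
            gk = grads[k] + self.weight_decay * param
            self.m[k] = b1 * self.m[k] + (1 - b1) * gk
            self.v[k] = b2 * self.v[k] + (1 - b2) * gk * gk
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            param -= lr * mhat / (np.sqrt(vhat) + self.eps)


def batch_adjacency(networks, p: int) -> sp.csr_matrix:
    """Block-diagonal directed adjacency for a batch of cell networks.

    Each undirected stored edge (u < v) is expanded to both directions with
    its weight, and graph b's nodes are offset by b*p.
    """
    rows, cols, vals = [], [], []
    for b, net in enumerate(networks):
        off = b * p
        rows.append(net.u + off)
        cols.append(net.v + off)
        rows.append(net.v + off)
        cols.append(net.u + off)
        vals.append(net.weight)
        vals.append(net.weight)
    if rows:
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
    else:  # pragma: no cover - empty batch
        rows = cols = vals = np.empty(0)
    n = len(networks) * p
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
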