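"""Baseline graph encoders: GCN, GAT, GraphSAGE.

These single-relation encoders collapse the typed relation sets of the DDI
graph into one untyped adjacency (the formulations below are single-
relation); relation information reaches them only through the shared
edge-feature classification head.

GCN:      H' = sigma(D~^{-1/2} A~ D~^{-1/2} H W),  A~ = A + I.
GAT:      a_ij = softmax_j(LeakyReLU(a^T [W h_i || W h_j])) over N(i),
          H'_i = sum_j a_ij W h_j.
GraphSAGE mean:    h'_v = sigma(W . MEAN({h_v} U {h_u, u in N(v)}))
GraphSAGE pooling: h'_v = max({sigma(W_pool h_u + b), u in N(v)}).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat
from .layers import glorot


@dataclass(frozen=True)
class BaselineConfig:
    encoder: str = "gcn"            # gcn | gat | sage
    layers: int = 2
    width: int = 128
    sage_aggregator: str = "mean"   # mean | pooling
    gat_heads: int = 1

    def __post_init__(self):
        if self.encoder not in ("gcn", "gat", "sage"):
            raise ValueError(f"unknown encoder {self.encoder!r}")
        if self.layers < 1 or self.width <= 0:
            raise ValueError("layers >= 1 and width > 0 required")
        if self.sage_aggregator not in ("mean", "pooling"):
            raise ValueError(f"unknown aggregator {self.sage_aggregator!r}")


def collapse_relations(relations: list[np.ndarray], n_nodes: int) -> np.ndarray:
    """Untyped dense 0/1 adjacency from typed double-entry arc lists."""
    A = np.zeros((n_nodes, n_nodes))
    for arcs in relations:
        if len(arcs):
            A[arcs[:, 0], arcs[:, 1]] = 1.0
    return A


def normalized_adjacency(A: np.ndarray) -> np.ndarray:
    """D~^{-1/2} (A + I) D~^{-1/2} with D~ the degree matrix of A + I."""
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    At = A + np.eye(A.shape[0], dtype=A.dtype)
    dinv = 1.0 / np.sqrt(At.sum(axis=1))
    return At * dinv[:, None] * dinv[None, :]


def gcn_layer(adjacency: np.ndarray, H: Tensor, W: Tensor,
              activation=None) -> Tensor:
    """Symmetric-normalized propagation with self-loops added."""
    Ahat = Tensor(normalized_adjacency(adjacency).astype(H.data.dtype))
    out = Ahat @ H @ W
    return activation(out) if activation is not None else out


def _adjacency_arcs(adjacency: np.ndarray, self_loops: bool) -> np.ndarray:
    A = np.asarray(adjacency)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if self_loops:
        A = A + np.eye(A.shape[0], dtype=A.dtype)
    src, dst = np.nonzero(A)  # arc j -> i aggregated at i = dst? see caller
    return np.stack([src, dst], axis=1)


def gat_layer(adjacency: np.ndarray, H: Tensor, W: Tensor, a: Tensor,
              slope: float = 0.2, activation=None) -> Tensor:
    """Single-head graph attention over neighbors (self-loops added so
    isolated nodes attend to themselves)."""
    n = adjacency.shape[0]
    arcs = _adjacency_arcs(adjacency, self_loops=True)
    i_idx, j_idx = arcs[:, 1], arcs[:, 0]       # node i attends over j
    Wh = H @ W.T
    d_out = Wh.shape[1]
    a1 = a.gather_rows(np.arange(d_out))        # split scorer a = [a1; a2]
    a2 = a.gather_rows(np.arange(d_out, 2 * d_out))
    s = (Wh @ a1.reshape(-1, 1)).gather_rows(i_idx) \
        + (Wh @ a2.reshape(-1, 1)).gather_rows(j_idx)
    s = s.leaky_relu(slope)
    smax = np.full(n, -np.inf, dtype=s.data.dtype)
    np.maximum.at(smax, i_idx, s.data[:, 0])    # detached shift for stability
    e = (s - Tensor(smax[i_idx][:, None])).exp()
    denom = e.segment_sum(i_idx, n)
    coeff = e * denom.gather_rows(i_idx) ** -1.0
    out = (Wh.gather_rows(j_idx) * coeff).segment_sum(i_idx, n)
    return activation(out) if activation is not None else out


def gat_coefficients(adjacency: np.ndarray, H: np.ndarray, W: np.ndarray,
                     a: np.ndarray, slope: float = 0.2) -> dict:
    """Attention coefficients a_ij keyed by (i, j), for inspection."""
    n = adjacency.shape[0]
    arcs = _adjacency_arcs(adjacency, self_loops=True)
    i_idx, j_idx = arcs[:, 1], arcs[:, 0]
    Wh = H @ W.T
    d_out = Wh.shape[1]
    s = Wh[i_idx] @ a[:d_out] + Wh[j_idx] @ a[d_out:]
    s = np.where(s > 0, s, slope * s)
    coeffs = {}
    for i in range(n):
        mask = i_idx == i
        e = np.exp(s[mask] - s[mask].max())
        for j, c in zip(j_idx[mask], e / e.sum()):
            coeffs[(i, int(j))] = float(c)
    return coeffs


def sage_layer(adjacency: np.ndarray, H: Tensor, W: Tensor,
               bias: Tensor | None = None, aggregator: str = "mean",
               activation=None) -> Tensor:
    """GraphSAGE aggregation.

    mean:    average the self state with neighbor states, then project.
    pooling: project every neighbor through the fully connected layer
             (with bias and the activation inside the max), then take the
             element-wise max; nodes without neighbors yield zeros.
    """
    n = adjacency.shape[0]
    if aggregator == "mean":
        arcs = _adjacency_arcs(adjacency, self_loops=True)
        i_idx, j_idx = arcs[:, 1], arcs[:, 0]
        counts = np.bincount(i_idx, minlength=n).astype(H.data.dtype)
        agg = H.gather_rows(j_idx).segment_sum(i_idx, n) \
            * Tensor((1.0 / np.maximum(counts, 1.0))[:, None])
        out = agg @ W.T
        return activation(out) if activation is not None else out
    if aggregator == "pooling":
        arcs = _adjacency_arcs(adjacency, self_loops=False)
        i_idx, j_idx = arcs[:, 1], arcs[:, 0]
        proj = H @ W.T
        if bias is not None:
            proj = proj + bias
        proj = activation(proj) if activation is not None else proj
        return proj.gather_rows(j_idx).segment_max(i_idx, n)
    raise ValueError(f"unknown aggregator {aggregator!r}")


@dataclass
class BaselineModel:
    """A baseline encoder stack plus the shared edge-classification head.

    The head mirrors the main model's edge re-embedding (endpoint states
    plus a projection of the edge attribute, then a linear scorer) but has
    no attention block.
    """

    config: BaselineConfig
    n_classes: int
    in_dim: int
    edge_dim: int
    seed: int = 0
    dtype: type = np.float64

    weights: list[dict[str, Tensor]] = field(init=False)
    edge_embed: Tensor = field(init=False)
    head_W: Tensor = field(init=False)
    head_b: Tensor = field(init=False)

    def __post_init__(self):
        rng = np.random.default_rng(self.seed)
        cfg = self.config
        dims = [self.in_dim] + [cfg.width] * cfg.layers
        self.weights = []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            layer: dict[str, Tensor] = {}
            if cfg.encoder == "gcn":
                layer["W"] = glorot(rng, (d_in, d_out), self.dtype)
            elif cfg.encoder == "gat":
                if d_out % cfg.gat_heads:
                    raise ValueError("width not divisible by gat_heads")
                dh = d_out // cfg.gat_heads
                for h in range(cfg.gat_heads):
                    layer[f"W{h}"] = glorot(rng, (dh, d_in), self.dtype)
                    layer[f"a{h}"] = glorot(rng, (2 * dh, 1), self.dtype).reshape(-1)
            else:  # sage
                layer["W"] = glorot(rng, (d_out, d_in), self.dtype)
                if cfg.sage_aggregator == "pooling":
                    layer["b"] = Tensor(np.zeros(d_out, dtype=self.dtype),
                                        requires_grad=True)
            self.weights.append(layer)
        self.edge_embed = glorot(rng, (cfg.width, self.edge_dim), self.dtype)
        self.head_W = glorot(rng, (self.n_classes, cfg.width), self.dtype)
        self.head_b = Tensor(np.zeros(self.n_classes, dtype=self.dtype),
                             requires_grad=True)

    def parameters(self) -> dict[str, Tensor]:
        out = {}
        for li, layer in enumerate(self.weights):
            for k, v in layer.items():
                out[f"l{li}.{k}"] = v
        out.update({"edge_embed": self.edge_embed,
                    "head.W": self.head_W, "head.b": self.head_b})
        return out

    def node_embeddings(self, adjacency: np.ndarray, X: np.ndarray) -> Tensor:
        h = Tensor(X.astype(self.dtype))
        cfg = self.config
        for li, layer in enumerate(self.weights):
            act = Tensor.relu if li < len(self.weights) - 1 else None
            if cfg.encoder == "gcn":
                h = gcn_layer(adjacency, h, layer["W"], activation=act)
            elif cfg.encoder == "gat":
                heads = [gat_layer(adjacency, h, layer[f"W{i}"], layer[f"a{i}"])
                         for i in range(cfg.gat_heads)]
                h = heads[0] if len(heads) == 1 else concat(heads, axis=1)
                h = act(h) if act is not None else h
            else:
                h = sage_layer(adjacency, h, layer["W"], layer.get("b"),
                               cfg.sage_aggregator,
                               activation=Tensor.relu
                               if cfg.sage_aggregator == "pooling" else None)
                if cfg.sage_aggregator == "mean" and act is not None:
                    h = act(h)
        return h

    def edge_scores(self, relations: list[np.ndarray], X: np.ndarray,
                    edge_features: list[np.ndarray] | None,
                    query_edges: np.ndarray,
                    query_edge_features: np.ndarray | None) -> Tensor:
        A = collapse_relations(relations, X.shape[0])
        H = self.node_embeddings(A, X)
        q = np.asarray(query_edges, dtype=np.int64).reshape(-1, 2)
        z = H.gather_rows(q[:, 0]) + H.gather_rows(q[:, 1])
        if query_edge_features is not None:
            ef = Tensor(np.asarray(query_edge_features, dtype=self.dtype))
            z = z + ef @ self.edge_embed.T
        return z @ self.head_W.T + self.head_b
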