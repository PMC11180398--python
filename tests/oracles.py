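"""Independent dense re-implementations used as oracles.

Everything here is written with explicit Python loops over dense arrays and
never calls into the package's layer code, so agreement between the two
routes is a meaningful check.
"""

from __future__ import annotations

import numpy as np


def dense_rgcn_layer(adj_r: list[np.ndarray], X: np.ndarray,
                     W0: np.ndarray, Wr: list[np.ndarray],
                     E: np.ndarray | None,
                     edge_attr: dict | None,
                     activation=None) -> np.ndarray:
    """Per-node loop RGCN: out_i = act(W0 x_i + sum_r sum_j (1/c) W_r fuse).

    ``adj_r[r]`` is a dense 0/1 matrix with adj[i, j] = 1 when j is an
    in-neighbor of i under relation r; ``edge_attr[(r, i, j)]`` the arc
    attribute for the arc j -> i.
    """
    n, _ = X.shape
    out = np.zeros((n, W0.shape[0]))
    for i in range(n):
        acc = W0 @ X[i]
        for r, A in enumerate(adj_r):
            nbrs = np.nonzero(A[i])[0]
            if len(nbrs) == 0:
                continue
            c = len(nbrs)
            for j in nbrs:
                fuse = X[j].copy()
                if E is not None:
                    fuse = fuse + E @ edge_attr[(r, i, j)]
                acc = acc + (Wr[r] @ fuse) / c
        out[i] = acc
    if activation is not None:
        out = activation(out)
    return out


def dense_multi_head_attention(Z: np.ndarray, Wq, Wk, Wv, Wo,
                               n_heads: int, learned_value: bool
                               ) -> np.ndarray:
    """Per-head, per-query loop attention."""
    L, d = Z.shape
    dk = d // n_heads
    Q, K = Z @ Wq, Z @ Wk
    V = Z @ Wv if learned_value else Z
    heads = []
    for h in range(n_heads):
        sl = slice(h * dk, (h + 1) * dk)
        out_h = np.zeros((L, dk))
        for i in range(L):
            scores = np.array([Q[i, sl] @ K[j, sl] for j in range(L)]) / np.sqrt(dk)
            scores = scores - scores.max()
            w = np.exp(scores)
            w = w / w.sum()
            out_h[i] = sum(w[j] * V[j, sl] for j in range(L))
        heads.append(out_h)
    return np.concatenate(heads, axis=1) @ Wo


def dense_layer_norm(X: np.ndarray, gamma, beta, eps) -> np.ndarray:
    out = np.zeros_like(X, dtype=float)
    for i in range(X.shape[0]):
        mu = X[i].mean()
        var = ((X[i] - mu) ** 2).mean()
        out[i] = (X[i] - mu) / np.sqrt(var + eps) * gamma + beta
    return out


def dense_gcn_layer(A: np.ndarray, H: np.ndarray, W: np.ndarray) -> np.ndarray:
    n = A.shape[0]
    At = A + np.eye(n)
    D = np.diag(At.sum(axis=1))
    Dinv = np.diag(1.0 / np.sqrt(np.diag(D)))
    return Dinv @ At @ Dinv @ H @ W


def dense_gat_layer(A: np.ndarray, H: np.ndarray, W: np.ndarray,
                    a: np.ndarray, slope: float = 0.2) -> np.ndarray:
    n = A.shape[0]
    At = A + np.eye(n)
    Wh = H @ W.T
    d = Wh.shape[1]
    out = np.zeros((n, d))
    for i in range(n):
        nbrs = np.nonzero(At[i])[0]
        scores = []
        for j in nbrs:
            s = a @ np.concatenate([Wh[i], Wh[j]])
            scores.append(s if s > 0 else slope * s)
        scores = np.array(scores)
        w = np.exp(scores - scores.max())
        w = w / w.sum()
        out[i] = sum(wj * Wh[j] for wj, j in zip(w, nbrs))
    return out


def dense_sage_layer(A: np.ndarray, H: np.ndarray, W: np.ndarray,
                     b: np.ndarray | None, aggregator: str,
                     activation=None) -> np.ndarray:
    n = A.shape[0]
    out = np.zeros((n, W.shape[0]))
    for v in range(n):
        nbrs = np.nonzero(A[v])[0]
        if aggregator == "mean":
            states = [H[v]] + [H[u] for u in nbrs]
            out[v] = W @ np.mean(states, axis=0)
        else:
            if len(nbrs) == 0:
                continue
            projs = []
            for u in nbrs:
                p = W @ H[u] + (b if b is not None else 0.0)
                if activation is not None:
                    p = activation(p)
                projs.append(p)
            out[v] = np.max(projs, axis=0)
    return out


def relations_to_dense(relations: list[np.ndarray], n: int
                       ) -> list[np.ndarray]:
    """adj[r][i, j] = 1 when the arc j -> i exists under relation r."""
    out = []
    for arcs in relations:
        A = np.zeros((n, n))
        for u, v in arcs:
            A[v, u] = 1.0
        out.append(A)
    return out
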