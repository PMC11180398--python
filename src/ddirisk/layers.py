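"""Attention-enhanced relational graph convolution for edge classification.

The encoder is a two-layer relational GCN over the heterogeneous DDI graph.
Each layer updates node i as

    x_i' = sigma( W_0 x_i + sum_r sum_{j in N_i^r} (1/c_ij) W_r (x_j + E w_ij) )

where r ranges over relation types (risk levels), w_ij is the arc's edge
attribute, E projects it into the layer's input space (the "edge
propagation" term; dropped under the ``no_ep`` ablation), and
c_ij = |N_i^r| is the per-relation in-degree normalizer.  Per-relation
weights W_r are regularized by either basis decomposition

    W_r = sum_b a_rb V_b          (only the coefficients depend on r)

or block-diagonal decomposition W_r = diag(Q_r1, ..., Q_rB); with B = d
every block is 1x1 and W_r is diagonal.

After propagation, each query edge (i, j) is re-embedded by fusing its two
endpoint states with its own attribute, z_e = h_i + h_j + P w_e; the batch
of edge latents is refined by multi-head scaled dot-product attention
(softmax(QK^T/sqrt(d_k)) applied, in the printed-formula variant, to the
fused inputs themselves rather than a learned value projection) with a
residual connection and layer normalization, and finally scored by a linear
layer into R classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import AdamW, Tensor, concat  # noqa: F401  (AdamW re-export)

ABLATIONS = ("none", "no_fp", "no_at", "no_ep")


# ----------------------------------------------------------------- helpers

def glorot(rng: np.random.Generator, shape: tuple[int, ...],
           dtype=np.float64) -> Tensor:
    fan_in, fan_out = shape[-1], shape[-2] if len(shape) > 1 else shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape).astype(dtype),
                  requires_grad=True)


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax (row max subtracted before exp)."""
    shifted = t - Tensor(t.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e * e.sum(axis=axis, keepdims=True) ** -1.0


# --------------------------------------------------- relation weight factors

@dataclass
class RelationWeightFactors:
    """Factorized per-relation weights for one RGCN layer.

    mode 'basis':  W_r = sum_b coefficients[r, b] * bases[b]
    mode 'block':  W_r = block_diag(blocks[r][0], ..., blocks[r][B-1])
    mode 'full':   W_r unconstrained (stacked in ``full``)
    """

    mode: str
    self_weight: Tensor                       # W_0, (d_out, d_in)
    bases: Tensor | None = None               # (B, d_out, d_in)
    coefficients: Tensor | None = None        # (R, B)
    blocks: list[list[Tensor]] | None = None  # R x B, each (d_out/B, d_in/B)
    full: Tensor | None = None                # (R, d_out, d_in)
    edge_projection: Tensor | None = None     # E, (d_in, edge_dim)

    def __post_init__(self):
        if self.mode not in ("basis", "block", "full"):
            raise ValueError(f"unknown decomposition mode {self.mode!r}")

    @property
    def n_relations(self) -> int:
        if self.mode == "basis":
            return self.coefficients.shape[0]
        if self.mode == "block":
            return len(self.blocks)
        return self.full.shape[0]

    @property
    def out_dim(self) -> int:
        return self.self_weight.shape[0]

    def parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {f"{prefix}W0": self.self_weight}
        if self.mode == "basis":
            out[f"{prefix}V"] = self.bases
            out[f"{prefix}a"] = self.coefficients
        elif self.mode == "block":
            for r, row in enumerate(self.blocks):
                for b, q in enumerate(row):
                    out[f"{prefix}Q{r}_{b}"] = q
        else:
            out[f"{prefix}W"] = self.full
        if self.edge_projection is not None:
            out[f"{prefix}E"] = self.edge_projection
        return out

    @classmethod
    def create(cls, rng: np.random.Generator, mode: str, n_relations: int,
               d_in: int, d_out: int, num_bases: int | None = None,
               edge_dim: int | None = None, dtype=np.float64
               ) -> "RelationWeightFactors":
        B = num_bases if num_bases is not None else n_relations
        W0 = glorot(rng, (d_out, d_in), dtype)
        E = glorot(rng, (d_in, edge_dim), dtype) if edge_dim else None
        if mode == "basis":
            return cls(mode, W0, bases=glorot(rng, (B, d_out, d_in), dtype),
                       coefficients=glorot(rng, (n_relations, B), dtype),
                       edge_projection=E)
        if mode == "block":
            if d_in % B or d_out % B:
                raise ValueError(
                    f"block mode needs B={B} to divide d_in={d_in} and "
                    f"d_out={d_out}")
            blocks = [[glorot(rng, (d_out // B, d_in // B), dtype)
                       for _ in range(B)] for _ in range(n_relations)]
            return cls(mode, W0, blocks=blocks, edge_projection=E)
        return cls(mode, W0, full=glorot(rng, (n_relations, d_out, d_in), dtype),
                   edge_projection=E)


def _block_diag(blocks: list[Tensor]) -> Tensor:
    """Direct sum of square-ish blocks; off-block entries are exactly zero."""
    rows = []
    for i, q in enumerate(blocks):
        br, bc = q.shape
        row = [q if j == i
               else Tensor(np.zeros((br, blocks[j].shape[1]), dtype=q.data.dtype))
               for j in range(len(blocks))]
        rows.append(concat(row, axis=1))
    return concat(rows, axis=0)


def materialize_relation_weights(factors: RelationWeightFactors) -> list[Tensor]:
    """Dense W_r for every relation, differentiable through the factors."""
    R = factors.n_relations
    if factors.mode == "basis":
        B, d_out, d_in = factors.bases.shape
        flat = factors.coefficients @ factors.bases.reshape(B, d_out * d_in)
        return [flat.gather_rows(np.array([r])).reshape(d_out, d_in)
                for r in range(R)]
    if factors.mode == "block":
        return [_block_diag(factors.blocks[r]) for r in range(R)]
    d_out, d_in = factors.full.shape[1:]
    return [factors.full.gather_rows(np.array([r])).reshape(d_out, d_in)
            for r in range(R)]


# -------------------------------------------------------------- propagation

def edge_message(node_states: Tensor, edge_feature: np.ndarray | None,
                 arc: tuple[int, int], weight: Tensor,
                 edge_projection: Tensor | None) -> Tensor:
    """Message along one directed arc (u -> v): W_r (x_u + E w_e).

    The edge-feature term is omitted when ``edge_projection`` is None (the
    edge-propagation ablation); otherwise a missing feature is an error.
    """
    u, _v = arc
    x_u = node_states.gather_rows(np.array([u]))
    if edge_projection is not None:
        if edge_feature is None:
            raise ValueError("edge feature required unless edge propagation "
                             "is ablated")
        x_u = x_u + Tensor(np.asarray(edge_feature)[None, :]) @ edge_projection.T
    return (x_u @ weight.T).reshape(-1)


def rgcn_layer_forward(relations: list[np.ndarray], node_states: Tensor,
                       edge_features: list[np.ndarray] | None,
                       factors: RelationWeightFactors,
                       activation=None, use_edge_features: bool = True
                       ) -> Tensor:
    """One relational graph convolution over directed double-entry arcs.

    ``relations[r]`` is an (m_r, 2) arc array; ``edge_features[r]`` the
    matching per-arc attribute matrix.  Nodes without neighbors receive the
    self-term only.  ``activation`` is a callable on Tensors (None for
    identity).
    """
    n = node_states.shape[0]
    if factors.self_weight.shape[1] != node_states.shape[1]:
        raise ValueError("node state width does not match layer input dim")
    out = node_states @ factors.self_weight.T
    weights = materialize_relation_weights(factors)
    dtype = node_states.data.dtype
    for r, arcs in enumerate(relations):
        if len(arcs) == 0:
            continue
        u, v = arcs[:, 0], arcs[:, 1]
        fuse = node_states.gather_rows(u)
        if use_edge_features and factors.edge_projection is not None:
            if edge_features is None or edge_features[r] is None:
                raise ValueError(f"missing edge features for relation {r}")
            ef = Tensor(np.asarray(edge_features[r], dtype=dtype))
            fuse = fuse + ef @ factors.edge_projection.T
        msg = fuse @ weights[r].T
        deg = np.bincount(v, minlength=n).astype(dtype)
        coeff = 1.0 / np.maximum(deg, 1.0)
        msg = msg * Tensor(coeff[v][:, None])
        out = out + msg.segment_sum(v, n)
    return activation(out) if activation is not None else out


# ---------------------------------------------------------------- attention

@dataclass
class AttentionParams:
    n_heads: int
    Wq: Tensor
    Wk: Tensor
    Wv: Tensor
    Wo: Tensor
    value_mode: str = "sum_inputs"  # or "learned"

    def __post_init__(self):
        d = self.Wq.shape[0]
        if d % self.n_heads:
            raise ValueError(f"width {d} not divisible by {self.n_heads} heads")
        if self.value_mode not in ("sum_inputs", "learned"):
            raise ValueError(f"unknown value mode {self.value_mode!r}")

    def parameters(self, prefix: str = "") -> dict[str, Tensor]:
        return {f"{prefix}Wq": self.Wq, f"{prefix}Wk": self.Wk,
                f"{prefix}Wv": self.Wv, f"{prefix}Wo": self.Wo}

    @classmethod
    def create(cls, rng: np.random.Generator, width: int, n_heads: int,
               value_mode: str = "sum_inputs", dtype=np.float64
               ) -> "AttentionParams":
        return cls(n_heads, *(glorot(rng, (width, width), dtype)
                              for _ in range(4)), value_mode=value_mode)


def multi_head_attention(Z: Tensor, params: AttentionParams) -> Tensor:
    """Scaled dot-product attention over a batch of edge latents.

    Per head h: A_h = softmax(Q_h K_h^T / sqrt(d_k)); the value sequence is
    the raw latents Z themselves in ``sum_inputs`` mode (the printed-formula
    variant, Z being the fused x_1 + x_2 edge inputs) or a learned
    projection Z Wv in ``learned`` mode.  Heads are concatenated and
    output-projected.
    """
    L, d = Z.shape
    H = params.n_heads
    dk = d // H

    def split(t: Tensor) -> Tensor:
        return t.reshape(L, H, dk).transpose(1, 0, 2)  # (H, L, dk)

    Q = split(Z @ params.Wq)
    K = split(Z @ params.Wk)
    V = split(Z @ params.Wv) if params.value_mode == "learned" else split(Z)
    scores = (Q @ K.transpose(0, 2, 1)) * (1.0 / np.sqrt(dk))
    attn = softmax(scores, axis=-1)            # rows sum to 1 per head
    out = (attn @ V).transpose(1, 0, 2).reshape(L, d)
    return out @ params.Wo


def attention_weights(Z: np.ndarray, params: AttentionParams) -> np.ndarray:
    """Per-head attention matrices (H, L, L) for inspection/testing."""
    L, d = Z.shape
    H = params.n_heads
    dk = d // H
    Q = (Z @ params.Wq.data).reshape(L, H, dk).transpose(1, 0, 2)
    K = (Z @ params.Wk.data).reshape(L, H, dk).transpose(1, 0, 2)
    s = Q @ K.transpose(0, 2, 1) / np.sqrt(dk)
    s = s - s.max(axis=-1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=-1, keepdims=True)


# --------------------------------------------------------------- layer norm

@dataclass
class LayerNormParams:
    gain: Tensor
    bias: Tensor
    eps: float = 1e-5

    def __post_init__(self):
        if self.eps <= 0:
            raise ValueError("eps must be positive")

    def parameters(self, prefix: str = "") -> dict[str, Tensor]:
        return {f"{prefix}gamma": self.gain, f"{prefix}beta": self.bias}

    @classmethod
    def create(cls, width: int, dtype=np.float64) -> "LayerNormParams":
        return cls(Tensor(np.ones(width, dtype=dtype), requires_grad=True),
                   Tensor(np.zeros(width, dtype=dtype), requires_grad=True))


def layer_norm(X: Tensor, params: LayerNormParams) -> Tensor:
    """(X - E[X]) / sqrt(Var[X] + eps) * gamma + beta, per row."""
    mu = X.mean(axis=-1, keepdims=True)
    xc = X - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc * (var + params.eps) ** -0.5 * params.gain + params.bias


# ------------------------------------------------------------ the full model

@dataclass
class AERGCN:
    """Two-layer relational GCN encoder with an attentive edge head.

    Ablation flags: ``no_at`` replaces the attention block by identity;
    ``no_ep`` drops every edge-attribute term (message fusion and edge
    re-embedding); ``no_fp`` is handled upstream by swapping node features
    for one-hot topology-only rows and is a no-op at this level.
    """

    n_relations: int
    in_dim: int
    edge_dim: int
    hidden: int = 128
    n_heads: int = 4
    num_bases: int | None = None
    decomposition: str = "basis"
    value_mode: str = "sum_inputs"
    ablation: str = "none"
    attn_batch_size: int = 512
    seed: int = 0
    dtype: type = np.float64

    layer1: RelationWeightFactors = field(init=False)
    layer2: RelationWeightFactors = field(init=False)
    attn: AttentionParams = field(init=False)
    norm: LayerNormParams = field(init=False)
    head_W: Tensor = field(init=False)
    head_b: Tensor = field(init=False)
    edge_embed: Tensor = field(init=False)

    def __post_init__(self):
        if self.ablation not in ABLATIONS:
            raise ValueError(f"unknown ablation flag {self.ablation!r}; "
                             f"expected one of {ABLATIONS}")
        rng = np.random.default_rng(self.seed)
        edge_dim = None if self.ablation == "no_ep" else self.edge_dim
        mode = {"block_diagonal": "block"}.get(self.decomposition,
                                               self.decomposition)
        self.layer1 = RelationWeightFactors.create(
            rng, mode, self.n_relations, self.in_dim, self.hidden,
            self.num_bases, edge_dim, self.dtype)
        self.layer2 = RelationWeightFactors.create(
            rng, mode, self.n_relations, self.hidden, self.hidden,
            self.num_bases, edge_dim, self.dtype)
        self.attn = AttentionParams.create(rng, self.hidden, self.n_heads,
                                           self.value_mode, self.dtype)
        self.norm = LayerNormParams.create(self.hidden, self.dtype)
        self.edge_embed = glorot(rng, (self.hidden, self.edge_dim), self.dtype)
        self.head_W = glorot(rng, (self.n_relations, self.hidden), self.dtype)
        self.head_b = Tensor(np.zeros(self.n_relations, dtype=self.dtype),
                             requires_grad=True)

    def parameters(self) -> dict[str, Tensor]:
        out = {}
        out.update(self.layer1.parameters("l1."))
        out.update(self.layer2.parameters("l2."))
        if self.ablation != "no_at":
            out.update(self.attn.parameters("at."))
            out.update(self.norm.parameters("ln."))
        if self.ablation != "no_ep":
            out["edge_embed"] = self.edge_embed
        out["head.W"] = self.head_W
        out["head.b"] = self.head_b
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters().values())

    # -- forward pieces ----------------------------------------------------
    def node_embeddings(self, relations: list[np.ndarray], X: np.ndarray,
                        edge_features: list[np.ndarray] | None) -> Tensor:
        use_ef = self.ablation != "no_ep"
        h = rgcn_layer_forward(relations, Tensor(X.astype(self.dtype)),
                               edge_features, self.layer1,
                               activation=Tensor.relu, use_edge_features=use_ef)
        return rgcn_layer_forward(relations, h, edge_features, self.layer2,
                                  activation=None, use_edge_features=use_ef)

    def edge_latents(self, H: Tensor, query_edges: np.ndarray,
                     query_edge_features: np.ndarray | None) -> Tensor:
        q = np.asarray(query_edges, dtype=np.int64).reshape(-1, 2)
        z = H.gather_rows(q[:, 0]) + H.gather_rows(q[:, 1])
        if self.ablation != "no_ep":
            if query_edge_features is None:
                raise ValueError("query edge features required unless the "
                                 "edge-propagation ablation is active")
            ef = Tensor(np.asarray(query_edge_features, dtype=self.dtype))
            z = z + ef @ self.edge_embed.T
        return z

    def refine(self, z: Tensor) -> Tensor:
        """Attention + residual + layer norm, in batches of edge latents."""
        if self.ablation == "no_at":
            return z
        L = z.shape[0]
        chunks = []
        for lo in range(0, L, self.attn_batch_size):
            zb = z.gather_rows(np.arange(lo, min(lo + self.attn_batch_size, L)))
            chunks.append(layer_norm(zb + multi_head_attention(zb, self.attn),
                                     self.norm))
        return chunks[0] if len(chunks) == 1 else concat(chunks, axis=0)

    def edge_scores(self, relations: list[np.ndarray], X: np.ndarray,
                    edge_features: list[np.ndarray] | None,
                    query_edges: np.ndarray,
                    query_edge_features: np.ndarray | None) -> Tensor:
        """Class logits for query edges: encode, re-embed, refine, score."""
        H = self.node_embeddings(relations, X, edge_features)
        z = self.edge_latents(H, query_edges, query_edge_features)
        z = self.refine(z)
        return z @ self.head_W.T + self.head_b
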