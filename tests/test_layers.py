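import numpy as np
import pytest

from ddirisk.autodiff import Tensor
from ddirisk.featurize import assemble_edge_features
from ddirisk.layers import (AERGCN, AttentionParams, LayerNormParams,
                            RelationWeightFactors, attention_weights,
                            edge_message, layer_norm,
                            materialize_relation_weights,
                            multi_head_attention, rgcn_layer_forward)
from ddirisk.train import _message_graph

from oracles import (dense_layer_norm, dense_multi_head_attention,
                     dense_rgcn_layer, relations_to_dense)


def _basis_factors(rng, R, B, d_in, d_out, edge_dim=None):
    return RelationWeightFactors.create(rng, "basis", R, d_in, d_out,
                                        num_bases=B, edge_dim=edge_dim)


class TestDecompositions:
    def test_single_basis_proportional(self, rng):
        f = _basis_factors(rng, R=3, B=1, d_in=4, d_out=5)
        Ws = materialize_relation_weights(f)
        V = f.bases.data[0]
        for r, W in enumerate(Ws):
            np.testing.assert_allclose(W.data, f.coefficients.data[r, 0] * V)

    def test_basis_matches_loop_sum_oracle(self, rng):
        f = _basis_factors(rng, R=4, B=3, d_in=5, d_out=6)
        Ws = materialize_relation_weights(f)
        for r in range(4):
            expect = sum(f.coefficients.data[r, b] * f.bases.data[b]
                         for b in range(3))
            np.testing.assert_allclose(Ws[r].data, expect, atol=1e-12)

    def test_delta_coefficients_reproduce_unconstrained(self, rng):
        """Basis mode with B = R and identity coefficients is exactly a
        free per-relation weight set."""
        R, d = 3, 4
        f = _basis_factors(rng, R=R, B=R, d_in=d, d_out=d)
        f.coefficients.data = np.eye(R)
        Ws = materialize_relation_weights(f)
        for r in range(R):
            np.testing.assert_array_equal(Ws[r].data, f.bases.data[r])

    def test_block_b_equals_d_is_diagonal(self, rng):
        d = 6
        f = RelationWeightFactors.create(rng, "block", n_relations=2,
                                         d_in=d, d_out=d, num_bases=d)
        for W in materialize_relation_weights(f):
            off = W.data[~np.eye(d, dtype=bool)]
            assert (off == 0).all()
            assert (np.diag(W.data) != 0).any()

    def test_block_off_diagonal_exact_zero(self, rng):
        f = RelationWeightFactors.create(rng, "block", n_relations=2,
                                         d_in=6, d_out=6, num_bases=3)
        W = materialize_relation_weights(f)[0].data
        mask = np.kron(np.eye(3, dtype=bool), np.ones((2, 2), dtype=bool))
        assert (W[~mask] == 0).all()

    def test_block_requires_divisibility(self, rng):
        with pytest.raises(ValueError, match="divide"):
            RelationWeightFactors.create(rng, "block", 2, d_in=5, d_out=6,
                                         num_bases=3)

    def test_basis_parameter_count(self, rng):
        R, B, di, do = 5, 2, 8, 8
        f = _basis_factors(rng, R, B, di, do)
        n = sum(p.data.size for k, p in f.parameters().items() if k != "W0")
        assert n == R * B + B * di * do
        assert n < R * di * do  # fewer than unconstrained


class TestRGCNLayer:
    def test_edgeless_graph_self_term_only(self, rng):
        f = _basis_factors(rng, 2, 2, 4, 3)
        X = rng.normal(size=(5, 4))
        rels = [np.zeros((0, 2), dtype=np.int64)] * 2
        out = rgcn_layer_forward(rels, Tensor(X), None, f)
        np.testing.assert_allclose(out.data, X @ f.self_weight.data.T)

    def test_single_edge_hand_computation(self, rng):
        """One undirected edge, one relation, c = 1."""
        f = _basis_factors(rng, 1, 1, 3, 3)
        X = rng.normal(size=(2, 3))
        rels = [np.array([[0, 1], [1, 0]])]
        out = rgcn_layer_forward(rels, Tensor(X), None, f)
        W0, W = f.self_weight.data, materialize_relation_weights(f)[0].data
        np.testing.assert_allclose(out.data[0], W0 @ X[0] + W @ X[1],
                                   atol=1e-12)
        np.testing.assert_allclose(out.data[1], W0 @ X[1] + W @ X[0],
                                   atol=1e-12)

    def test_duplicate_edges_mean_invariant(self, rng):
        f = _basis_factors(rng, 1, 1, 3, 3)
        X = rng.normal(size=(4, 3))
        arcs = np.array([[0, 1], [1, 0], [2, 3], [3, 2]])
        out1 = rgcn_layer_forward([arcs], Tensor(X), None, f)
        out2 = rgcn_layer_forward([np.concatenate([arcs, arcs])], Tensor(X),
                                  None, f)
        np.testing.assert_allclose(out1.data, out2.data, atol=1e-12)

    def test_matches_dense_oracle_with_edge_features(self, rng):
        R, n, d_in, d_out, k = 3, 8, 5, 6, 2
        f = _basis_factors(rng, R, 2, d_in, d_out, edge_dim=2 * k)
        X = rng.normal(size=(n, d_in))
        feats = rng.normal(size=(n, k))
        pairs = np.array([[0, 1], [2, 3], [4, 5], [1, 2], [6, 7], [0, 6]])
        labels = np.array([0, 1, 2, 0, 1, 2])
        rels, efs = _message_graph(pairs, labels, n, R, feats)
        out = rgcn_layer_forward(rels, Tensor(X), efs, f,
                                 activation=Tensor.relu)
        adj = relations_to_dense(rels, n)
        edge_attr = {}
        for r, arcs in enumerate(rels):
            for (u, v), w in zip(arcs, efs[r]):
                edge_attr[(r, v, u)] = w
        expect = dense_rgcn_layer(
            adj, X, f.self_weight.data,
            [W.data for W in materialize_relation_weights(f)],
            f.edge_projection.data, edge_attr,
            activation=lambda z: np.maximum(z, 0))
        np.testing.assert_allclose(out.data, expect, atol=1e-5)

    def test_permutation_equivariance(self, rng):
        R, n, d = 2, 7, 4
        f = _basis_factors(rng, R, 2, d, d)
        X = rng.normal(size=(n, d))
        pairs = np.array([[0, 1], [2, 3], [4, 5], [5, 6]])
        labels = np.array([0, 1, 0, 1])
        rels, _ = _message_graph(pairs, labels, n, R, X)
        out = rgcn_layer_forward(rels, Tensor(X), None, f).data
        perm = rng.permutation(n)
        inv = np.argsort(perm)
        rels_p = [inv[arcs] if len(arcs) else arcs for arcs in rels]
        out_p = rgcn_layer_forward(rels_p, Tensor(X[perm]), None, f).data
        np.testing.assert_allclose(out_p, out[perm], atol=1e-10)


class TestEdgeMessage:
    def test_zero_inputs_zero_message(self, rng):
        f = _basis_factors(rng, 1, 1, 3, 3, edge_dim=4)
        m = edge_message(Tensor(np.zeros((2, 3))), np.zeros(4), (0, 1),
                         materialize_relation_weights(f)[0],
                         f.edge_projection)
        np.testing.assert_allclose(m.data, 0.0)

    def test_identity_weight_passthrough(self):
        W = Tensor(np.eye(3))
        x = np.array([[1.0, 2.0, 3.0], [0.0, 0.0, 0.0]])
        m = edge_message(Tensor(x), None, (0, 1), W, None)
        np.testing.assert_allclose(m.data, x[0])

    def test_missing_edge_feature_error(self, rng):
        f = _basis_factors(rng, 1, 1, 3, 3, edge_dim=4)
        with pytest.raises(ValueError, match="edge feature"):
            edge_message(Tensor(np.zeros((2, 3))), None, (0, 1),
                         materialize_relation_weights(f)[0],
                         f.edge_projection)

    def test_matches_dense_computation(self, rng):
        f = _basis_factors(rng, 1, 1, 4, 5, edge_dim=3)
        X = rng.normal(size=(3, 4))
        w = rng.normal(size=3)
        m = edge_message(Tensor(X), w, (2, 0),
                         materialize_relation_weights(f)[0],
                         f.edge_projection)
        expect = materialize_relation_weights(f)[0].data @ (
            X[2] + f.edge_projection.data @ w)
        np.testing.assert_allclose(m.data, expect, atol=1e-12)


class TestMultiHeadAttention:
    def test_singleton_sequence(self, rng):
        p = AttentionParams.create(rng, width=8, n_heads=2)
        Z = rng.normal(size=(1, 8))
        out = multi_head_attention(Tensor(Z), p)
        np.testing.assert_allclose(out.data, Z @ p.Wo.data, atol=1e-12)
        assert attention_weights(Z, p)[:, 0, 0] == pytest.approx(1.0)

    def test_equal_keys_uniform_weights(self, rng):
        p = AttentionParams.create(rng, width=8, n_heads=2)
        Z = np.tile(rng.normal(size=(1, 8)), (5, 1))
        w = attention_weights(Z, p)
        np.testing.assert_allclose(w, 1.0 / 5, atol=1e-12)

    def test_rows_sum_to_one(self, rng):
        p = AttentionParams.create(rng, width=12, n_heads=3)
        w = attention_weights(rng.normal(size=(7, 12)), p)
        np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-12)

    @pytest.mark.parametrize("value_mode", ["sum_inputs", "learned"])
    def test_matches_loop_oracle(self, rng, value_mode):
        p = AttentionParams.create(rng, width=8, n_heads=2,
                                   value_mode=value_mode)
        Z = rng.normal(size=(5, 8))
        out = multi_head_attention(Tensor(Z), p)
        expect = dense_multi_head_attention(
            Z, p.Wq.data, p.Wk.data, p.Wv.data, p.Wo.data, 2,
            learned_value=(value_mode == "learned"))
        np.testing.assert_allclose(out.data, expect, atol=1e-5)

    def test_width_head_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            AttentionParams.create(rng, width=10, n_heads=4)


class TestLayerNorm:
    def test_constant_vector_gives_beta(self):
        p = LayerNormParams.create(4)
        out = layer_norm(Tensor(np.full((2, 4), 7.0)), p)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_zero_gain_gives_bias(self, rng):
        p = LayerNormParams.create(4)
        p.gain.data = np.zeros(4)
        p.bias.data = np.array([1.0, 2.0, 3.0, 4.0])
        out = layer_norm(Tensor(rng.normal(size=(3, 4))), p)
        np.testing.assert_allclose(out.data, np.tile(p.bias.data, (3, 1)))

    def test_hand_computed_1234(self):
        p = LayerNormParams.create(4)
        p.eps = 1e-5
        out = layer_norm(Tensor(np.array([[1.0, 2.0, 3.0, 4.0]])), p)
        expect = (np.array([1.0, 2.0, 3.0, 4.0]) - 2.5) / np.sqrt(1.25 + 1e-5)
        np.testing.assert_allclose(out.data[0], expect, atol=1e-12)

    def test_standardizes(self, rng):
        p = LayerNormParams.create(16)
        out = layer_norm(Tensor(rng.normal(size=(5, 16)) * 3 + 2), p).data
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.var(axis=1), 1.0, atol=1e-3)

    def test_matches_dense_oracle(self, rng):
        p = LayerNormParams.create(6)
        p.gain.data = rng.normal(size=6)
        p.bias.data = rng.normal(size=6)
        X = rng.normal(size=(4, 6))
        out = layer_norm(Tensor(X), p)
        np.testing.assert_allclose(
            out.data, dense_layer_norm(X, p.gain.data, p.bias.data, p.eps),
            atol=1e-5)

    def test_eps_positive(self):
        with pytest.raises(ValueError):
            LayerNormParams(Tensor(np.ones(2)), Tensor(np.zeros(2)), eps=0.0)


class TestEdgeScores:
    @staticmethod
    def _tiny_instance(rng, ablation="none"):
        n, k, R = 6, 3, 3
        model = AERGCN(n_relations=R, in_dim=k, edge_dim=2 * k, hidden=8,
                       n_heads=2, seed=11, ablation=ablation,
                       attn_batch_size=4)
        feats = rng.normal(size=(n, k))
        pairs = np.array([[0, 1], [1, 2], [3, 4], [2, 4], [0, 5]])
        labels = np.array([0, 1, 2, 0, 1])
        rels, efs = _message_graph(pairs, labels, n, R, feats)
        qef = assemble_edge_features(feats, pairs)
        return model, feats, rels, efs, pairs, qef

    def test_zero_head_uniform_probabilities(self, rng):
        model, X, rels, efs, pairs, qef = self._tiny_instance(rng)
        model.head_W.data = np.zeros_like(model.head_W.data)
        model.head_b.data = np.zeros_like(model.head_b.data)
        logits = model.edge_scores(rels, X, efs, pairs, qef).data
        np.testing.assert_allclose(logits, 0.0)
        e = np.exp(logits)
        np.testing.assert_allclose(e / e.sum(1, keepdims=True), 1.0 / 3)

    def test_no_at_equals_identity_attention(self, rng):
        model, X, rels, efs, pairs, qef = self._tiny_instance(rng)
        ablated, _, _, _, _, _ = self._tiny_instance(
            np.random.default_rng(12345), ablation="no_at")
        # share every parameter both models have
        ps, pa = model.parameters(), ablated.parameters()
        for k in pa:
            pa[k].data = ps[k].data
        H = model.node_embeddings(rels, X, efs)
        z = model.edge_latents(H, pairs, qef)
        expect = (z @ model.head_W.T + model.head_b).data
        got = ablated.edge_scores(rels, X, efs, pairs, qef).data
        np.testing.assert_allclose(got, expect, atol=1e-10)

    def test_end_to_end_dense_oracle(self, rng):
        """Full pipeline against an independent dense recomputation."""
        model, X, rels, efs, pairs, qef = self._tiny_instance(rng)
        n = X.shape[0]
        adj = relations_to_dense(rels, n)
        edge_attr = [{}, {}]
        for r, arcs in enumerate(rels):
            for (u, v), w in zip(arcs, efs[r]):
                edge_attr[0][(r, v, u)] = w
                edge_attr[1][(r, v, u)] = w
        W1 = [W.data for W in
              np.array(materialize_relation_weights(model.layer1),
                       dtype=object)]
        W2 = [W.data for W in
              np.array(materialize_relation_weights(model.layer2),
                       dtype=object)]
        h1 = dense_rgcn_layer(adj, X, model.layer1.self_weight.data, W1,
                              model.layer1.edge_projection.data, edge_attr[0],
                              activation=lambda z: np.maximum(z, 0))
        h2 = dense_rgcn_layer(adj, h1, model.layer2.self_weight.data, W2,
                              model.layer2.edge_projection.data, edge_attr[1])
        z = np.array([h2[i] + h2[j] for i, j in pairs]) \
            + qef @ model.edge_embed.data.T
        refined = np.zeros_like(z)
        bs = model.attn_batch_size
        for lo in range(0, len(z), bs):
            zb = z[lo:lo + bs]
            att = dense_multi_head_attention(
                zb, model.attn.Wq.data, model.attn.Wk.data,
                model.attn.Wv.data, model.attn.Wo.data, model.n_heads,
                learned_value=False)
            refined[lo:lo + bs] = dense_layer_norm(
                zb + att, model.norm.gain.data, model.norm.bias.data,
                model.norm.eps)
        expect = refined @ model.head_W.data.T + model.head_b.data
        got = model.edge_scores(rels, X, efs, pairs, qef).data
        np.testing.assert_allclose(got, expect, atol=1e-5)

    def test_unknown_ablation_rejected(self):
        with pytest.raises(ValueError, match="ablation"):
            AERGCN(n_relations=2, in_dim=3, edge_dim=6, hidden=8,
                   ablation="no_xx")

    def test_no_ep_ignores_edge_features(self, rng):
        model, X, rels, efs, pairs, qef = self._tiny_instance(
            rng, ablation="no_ep")
        a = model.edge_scores(rels, X, efs, pairs, qef).data
        b = model.edge_scores(rels, X, None, pairs, None).data
        np.testing.assert_allclose(a, b)
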