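"""Graph-attention sublayer against a literal scalar implementation."""

import numpy as np
import pytest

from conftest import random_tree_parse
from relex.autodiff import Tensor
from relex.depgraph import build_word_adjacency
from relex.encoder import EncoderConfig, layer_norm
from relex.gat import (
    BertGATClassifier,
    GATConfig,
    gat_aggregate,
    gat_attention,
    gat_scores,
    gat_sublayer,
    init_gat_layer,
)


def leaky(x, slope=0.2):
    return np.where(x > 0, x, slope * x)


def gat_oracle(h, W, a, A, slope=0.2):
    """Triple-loop scores/coefficients/aggregation, following the concatenated
    attention-vector formulation verbatim.  W: (K,d,d), a: (K,2d)."""
    K, _, d_out = W.shape
    n = h.shape[0]
    es, alphas, agg = [], [], np.zeros((n, d_out))
    for k in range(K):
        Wh = h @ W[k]
        e = np.full((n, n), np.nan)
        for i in range(n):
            for j in range(n):
                if A[i, j]:
                    e[i, j] = leaky(a[k] @ np.concatenate([Wh[i], Wh[j]]), slope)
        alpha = np.zeros((n, n))
        for i in range(n):
            nbrs = [j for j in range(n) if A[i, j]]
            exps = np.exp([e[i, j] - max(e[i, m] for m in nbrs) for j in nbrs])
            for j, w in zip(nbrs, exps / exps.sum()):
                alpha[i, j] = w
        es.append(e)
        alphas.append(alpha)
        for i in range(n):
            for j in range(n):
                agg[i] += alpha[i, j] * Wh[j]
    return es, alphas, leaky(agg / K, slope)


def random_graph(rng, n):
    A = build_word_adjacency(random_tree_parse(rng, n))
    return A


class TestScores:
    def test_zero_attention_vector_gives_zero_scores(self, rng):
        config = GATConfig(n_heads=1)
        params = init_gat_layer(rng, config, 8)
        params.a.data[:] = 0.0
        A = random_graph(rng, 5)
        e = gat_scores(rng.normal(size=(5, 8)), params, A)[0]
        assert np.allclose(e[A.astype(bool)], 0.0)

    def test_identical_features_give_constant_scores(self, rng):
        config = GATConfig(n_heads=1)
        params = init_gat_layer(rng, config, 8)
        h = np.tile(rng.normal(size=(1, 8)), (6, 1))
        A = random_graph(rng, 6)
        e = gat_scores(h, params, A)[0]
        vals = e[A.astype(bool)]
        assert np.allclose(vals, vals[0])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_concat_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        config = GATConfig(n_heads=2)
        params = init_gat_layer(rng, config, 6)
        h = rng.normal(size=(6, 6))
        A = random_graph(rng, 6)
        es, _, _ = gat_oracle(h, params.W.data, params.a.data, A)
        got = gat_scores(h, params, A)
        for k in range(2):
            assert np.allclose(got[k][A.astype(bool)], es[k][A.astype(bool)], atol=1e-6)


class TestAttention:
    def test_self_loop_only_node(self, rng):
        params = init_gat_layer(rng, GATConfig(n_heads=1), 4)
        A = np.eye(3, dtype=np.int8)
        h = rng.normal(size=(3, 4))
        alpha = gat_attention(gat_scores(h, params, A), A)[0]
        assert np.allclose(np.diag(alpha), 1.0)

    def test_two_equal_neighbors_split_evenly(self, rng):
        params = init_gat_layer(rng, GATConfig(n_heads=1), 4)
        params.a.data[:] = 0.0  # all neighbor scores equal
        A = np.array([[1, 1, 1], [1, 1, 0], [1, 0, 1]], dtype=np.int8)
        h = rng.normal(size=(3, 4))
        alpha = gat_attention(gat_scores(h, params, A), A)[0]
        assert np.allclose(alpha[0], [1 / 3, 1 / 3, 1 / 3])
        assert np.allclose(alpha[1], [0.5, 0.5, 0.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_normalization_and_masking(self, seed):
        rng = np.random.default_rng(seed)
        params = init_gat_layer(rng, GATConfig(n_heads=2), 6)
        A = random_graph(rng, 7)
        h = rng.normal(size=(7, 6))
        for alpha in gat_attention(gat_scores(h, params, A), A):
            assert np.allclose(alpha.sum(axis=-1), 1.0, atol=1e-6)
            assert np.all(alpha[~A.astype(bool)] == 0.0)
            assert np.all(alpha >= 0.0)


class TestAggregate:
    def test_isolated_node_is_leaky_projection(self, rng):
        config = GATConfig(n_heads=1)
        params = init_gat_layer(rng, config, 4)
        A = np.eye(2, dtype=np.int8)
        h = rng.normal(size=(2, 4))
        out = gat_aggregate(gat_attention(gat_scores(h, params, A), A), h, params, config)
        assert np.allclose(out, leaky(h @ params.W.data[0]), atol=1e-10)

    def test_clique_with_identical_features_is_uniform(self, rng):
        config = GATConfig(n_heads=2)
        params = init_gat_layer(rng, config, 4)
        A = np.ones((4, 4), dtype=np.int8)
        h = np.tile(rng.normal(size=(1, 4)), (4, 1))
        out = gat_aggregate(gat_attention(gat_scores(h, params, A), A), h, params, config)
        assert np.allclose(out, out[0])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        config = GATConfig(n_heads=2)
        params = init_gat_layer(rng, config, 6)
        h = rng.normal(size=(5, 6))
        A = random_graph(rng, 5)
        _, _, expected = gat_oracle(h, params.W.data, params.a.data, A)
        alpha = gat_attention(gat_scores(h, params, A), A)
        assert np.allclose(gat_aggregate(alpha, h, params, config), expected, atol=1e-6)


class TestSublayer:
    def test_zeroed_projection_reduces_to_layer_norm(self, rng):
        config = GATConfig(n_heads=2)
        params = init_gat_layer(rng, config, 8)
        params.W.data[:] = 0.0
        A = random_graph(rng, 5)
        x = rng.normal(size=(5, 8))
        assert np.allclose(gat_sublayer(x, A, params, config), layer_norm(x, params.ln))

    def test_identity_adjacency_is_per_token(self, rng):
        """With no graph edges, perturbing token j never changes row i."""
        config = GATConfig(n_heads=2)
        params = init_gat_layer(rng, config, 8)
        A = np.eye(6, dtype=np.int8)
        x = rng.normal(size=(6, 8))
        base = gat_sublayer(x, A, params, config)
        x2 = x.copy()
        x2[3] += rng.normal(size=8)
        out = gat_sublayer(x2, A, params, config)
        keep = [i for i in range(6) if i != 3]
        assert np.allclose(base[keep], out[keep])
        assert not np.allclose(base[3], out[3])

    def test_deterministic(self, rng):
        config = GATConfig(n_heads=2)
        params = init_gat_layer(rng, config, 8)
        A = random_graph(rng, 6)
        x = rng.normal(size=(6, 8))
        assert np.array_equal(
            gat_sublayer(x, A, params, config), gat_sublayer(x, A, params, config)
        )


class TestClassifier:
    def test_probabilities_sum_to_one(self, rng):
        config = EncoderConfig(d_model=16, n_heads=2, n_layers=1, seed=0)
        model = BertGATClassifier(config, GATConfig(), vocab_size=12, labels=["a", "b", "c"])
        A = random_graph(rng, 4)
        # token sequence of length 4 to match the graph
        p = model.predict_proba([1, 2, 3, 4], A, entity_spans=([1], [2]))
        assert p.shape == (3,)
        assert p.sum() == pytest.approx(1.0, abs=1e-6)

    def test_zeroed_gat_matches_plain_encoder_with_extra_norm(self, rng):
        """With the GAT projection zeroed the model's pooled features equal
        the plain encoder output passed through the sublayer's LayerNorm."""
        from relex.encoder import encoder_forward

        config = EncoderConfig(d_model=16, n_heads=2, n_layers=1, seed=1)
        model = BertGATClassifier(
            config, GATConfig(), vocab_size=12, labels=["a", "b"], pooling="cls"
        )
        layer = model.gat_layers[0]
        layer.W.data[:] = 0.0
        A = random_graph(rng, 4)
        ids = [1, 5, 7, 2]
        got = model.logits(ids, A).data
        enc = encoder_forward(ids, config, model.encoder_params).data
        pooled = layer_norm(enc, layer.ln)[0]
        expected = pooled @ model.head.W.data + model.head.b.data
        assert np.allclose(got.reshape(-1), expected, atol=1e-10)

    def test_misaligned_adjacency_rejected(self, rng):
        from relex.gat import bert_gat_classify

        config = EncoderConfig(d_model=16, n_heads=2, n_layers=1, seed=2)
        model = BertGATClassifier(config, GATConfig(), vocab_size=12, labels=["a", "b"])
        with pytest.raises(ValueError, match="inst-7"):
            bert_gat_classify([1, 2, 3], np.eye(5, dtype=np.int8), model, instance_id="inst-7")
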