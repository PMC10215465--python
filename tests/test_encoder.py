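"""Transformer encoder blocks against literal scalar-loop oracles."""

import math

import numpy as np
import pytest

from relex.autodiff import Tensor
from relex.encoder import (
    EncoderConfig,
    SequenceLengthError,
    attention_weights,
    encoder_forward,
    ffn,
    init_encoder_params,
    init_ffn_params,
    init_attention_params,
    init_layernorm_params,
    layer_norm,
    multi_head_attention,
    positional_encoding,
    positional_encoding_table,
    residual_layernorm,
    scaled_dot_attention,
)


def sdpa_oracle(Q, K, V, mask=None):
    """Double-loop scaled dot-product attention, literally."""
    nq, d_k = Q.shape
    nk = K.shape[0]
    out = np.zeros((nq, V.shape[1]))
    for i in range(nq):
        scores = np.array(
            [
                -np.inf if (mask is not None and mask[i, j]) else Q[i] @ K[j] / math.sqrt(d_k)
                for j in range(nk)
            ]
        )
        w = np.exp(scores - scores.max())
        w = w / w.sum()
        for j in range(nk):
            out[i] += w[j] * V[j]
    return out


class TestScaledDotAttention:
    def test_single_position_returns_value_row(self, rng):
        Q, K, V = rng.normal(size=(1, 4)), rng.normal(size=(1, 4)), rng.normal(size=(1, 6))
        assert np.allclose(scaled_dot_attention(Q, K, V), V)

    def test_identical_keys_give_column_mean(self, rng):
        K = np.tile(rng.normal(size=(1, 4)), (5, 1))
        Q = rng.normal(size=(3, 4))
        V = rng.normal(size=(5, 6))
        out = scaled_dot_attention(Q, K, V)
        assert np.allclose(out, np.tile(V.mean(axis=0), (3, 1)))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        Q, K, V = (rng.normal(size=(4, 8)) for _ in range(3))
        assert np.allclose(scaled_dot_attention(Q, K, V), sdpa_oracle(Q, K, V), atol=1e-6)

    def test_masked_positions_get_zero_weight(self, rng):
        Q, K = rng.normal(size=(3, 4)), rng.normal(size=(5, 4))
        mask = np.zeros((3, 5), dtype=bool)
        mask[0, 2] = mask[2, 4] = True
        w = attention_weights(Q, K, mask=mask)
        assert w[0, 2] == 0.0 and w[2, 4] == 0.0
        assert np.allclose(w.sum(axis=-1), 1.0, atol=1e-6)

    def test_fully_masked_query_rejected(self, rng):
        Q, K, V = (rng.normal(size=(2, 4)) for _ in range(3))
        mask = np.zeros((2, 2), dtype=bool)
        mask[1, :] = True
        with pytest.raises(ValueError, match="masked"):
            scaled_dot_attention(Q, K, V, mask=mask)


class TestMultiHead:
    def test_single_head_identity_output_projection(self, rng):
        params = init_attention_params(rng, 8, 1, 8)
        params.W_O = Tensor(np.eye(8))
        X = rng.normal(size=(5, 8))
        direct = scaled_dot_attention(
            X @ params.W_Q.data[0], X @ params.W_K.data[0], X @ params.W_V.data[0]
        )
        assert np.allclose(multi_head_attention(X, params), direct, atol=1e-12)

    def test_permutation_equivariance(self, rng):
        params = init_attention_params(rng, 8, 2, 4)
        X = rng.normal(size=(6, 8))
        perm = rng.permutation(6)
        out = multi_head_attention(X, params)
        out_perm = multi_head_attention(X[perm], params)
        assert np.allclose(out[perm], out_perm, atol=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_per_head_loop(self, seed):
        rng = np.random.default_rng(seed)
        params = init_attention_params(rng, 8, 2, 4)
        X = rng.normal(size=(5, 8))
        heads = [
            sdpa_oracle(X @ params.W_Q.data[h], X @ params.W_K.data[h], X @ params.W_V.data[h])
            for h in range(2)
        ]
        expected = np.concatenate(heads, axis=-1) @ params.W_O.data
        assert np.allclose(multi_head_attention(X, params), expected, atol=1e-6)


class TestPositionalEncoding:
    def test_position_zero(self):
        v = positional_encoding(0, 16)
        assert np.allclose(v[0::2], 0.0)
        assert np.allclose(v[1::2], 1.0)

    def test_position_one_dim_zero(self):
        assert positional_encoding(1, 16)[0] == pytest.approx(math.sin(1.0), abs=1e-9)

    def test_table_matches_elementwise_loop(self):
        d_model = 16
        table = positional_encoding_table(64, d_model)
        for pos in range(64):
            for i in range(d_model // 2):
                angle = pos / 10000 ** (2 * i / d_model)
                assert table[pos, 2 * i] == pytest.approx(math.sin(angle), abs=1e-12)
                assert table[pos, 2 * i + 1] == pytest.approx(math.cos(angle), abs=1e-12)


class TestFFN:
    def test_identity_on_nonnegative(self):
        params = init_ffn_params(np.random.default_rng(0), 4, 4)
        params.W1.data = np.eye(4)
        params.W2.data = np.eye(4)
        X = np.abs(np.random.default_rng(1).normal(size=(3, 4)))
        assert np.allclose(ffn(X, params), X)

    def test_relu_kills_negative_preactivations(self, rng):
        params = init_ffn_params(rng, 4, 6)
        params.b1.data = np.full(6, -1e6)  # drive every preactivation negative
        X = rng.normal(size=(3, 4))
        assert np.allclose(ffn(X, params), np.tile(params.b2.data, (3, 1)))

    def test_matches_loop_oracle(self, rng):
        params = init_ffn_params(rng, 5, 7)
        params.b1.data = rng.normal(size=7)
        params.b2.data = rng.normal(size=5)
        X = rng.normal(size=(4, 5))
        expected = np.zeros((4, 5))
        for r in range(4):
            hidden = np.maximum(0.0, X[r] @ params.W1.data + params.b1.data)
            expected[r] = hidden @ params.W2.data + params.b2.data
        assert np.allclose(ffn(X, params), expected, atol=1e-9)


class TestLayerNorm:
    def test_negated_sublayer_gives_zero_rows(self, rng):
        ln = init_layernorm_params(8)
        X = rng.normal(size=(3, 8))
        out = residual_layernorm(X, -X, ln)
        assert np.allclose(out, 0.0)

    def test_constant_rows_normalize_to_zero(self):
        ln = init_layernorm_params(6)
        X = np.full((2, 6), 3.7)
        assert np.allclose(layer_norm(X, ln), 0.0, atol=1e-3)

    def test_matches_mean_var_loop(self, rng):
        ln = init_layernorm_params(8)
        ln.gain.data = rng.normal(size=8)
        ln.bias.data = rng.normal(size=8)
        X = rng.normal(size=(4, 8))
        S = rng.normal(size=(4, 8))
        expected = np.zeros_like(X)
        for r in range(4):
            v = X[r] + S[r]
            mu, var = v.mean(), v.var()
            expected[r] = (v - mu) / np.sqrt(var + ln.eps) * ln.gain.data + ln.bias.data
        assert np.allclose(residual_layernorm(X, S, ln), expected, atol=1e-9)


class TestEncoderForward:
    def test_zero_layers_is_embedding_plus_positions(self):
        config = EncoderConfig(d_model=8, n_heads=2, n_layers=0, seed=3)
        params = init_encoder_params(config, vocab_size=11)
        ids = [1, 4, 7]
        out = encoder_forward(ids, config, params)
        expected = params.embedding.data[ids] + positional_encoding_table(3, 8)
        assert np.allclose(out.data, expected)

    def test_determinism_in_eval_mode(self):
        config = EncoderConfig(d_model=16, n_heads=2, n_layers=2, seed=5)
        params = init_encoder_params(config, vocab_size=20)
        a = encoder_forward([3, 1, 2, 9], config, params).data
        b = encoder_forward([3, 1, 2, 9], config, params).data
        assert np.array_equal(a, b)

    def test_overlong_sequence_rejected(self):
        config = EncoderConfig(d_model=8, n_heads=2, max_len=4, seed=0)
        params = init_encoder_params(config, vocab_size=10)
        with pytest.raises(SequenceLengthError):
            encoder_forward([0] * 5, config, params)

    @pytest.mark.parametrize("seed", range(10))
    def test_finite_and_shape_preserving(self, seed):
        config = EncoderConfig(d_model=16, n_heads=2, n_layers=2, seed=seed)
        params = init_encoder_params(config, vocab_size=15)
        rng = np.random.default_rng(seed)
        ids = rng.integers(0, 15, size=rng.integers(1, 12)).tolist()
        out = encoder_forward(ids, config, params)
        assert out.shape == (len(ids), 16)
        assert np.all(np.isfinite(out.data))

    def test_config_invariant(self):
        with pytest.raises(ValueError):
            EncoderConfig(d_model=10, n_heads=3)
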