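"""From-scratch transformer encoder blocks at configurable dimension.

The encoder follows the canonical post-norm design: token embeddings plus
sinusoidal positional encodings feed a stack of layers, each consisting of a
multi-head scaled-dot-product self-attention sublayer and a position-wise
feed-forward sublayer, both wrapped as LayerNorm(x + Sublayer(x)).

All operations are implemented on the package's autodiff tensors so the
same code path serves both inference and training; the public functional
forms (`scaled_dot_attention`, `ffn`, ...) accept plain NumPy arrays and
return NumPy arrays, which is what the oracle-equivalence tests exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, embedding, parameter, softmax

MASK_SENTINEL = -1e30  # additive logit for disallowed attention positions


class SequenceLengthError(ValueError):
    """Raised (rather than silently truncating) for overlong inputs."""


@dataclass
class EncoderConfig:
    d_model: int = 32
    n_heads: int = 2
    d_ff: int = 64
    n_layers: int = 2
    dropout: float = 0.0
    max_len: int = 128
    seed: int = 0
    d_k: int | None = None  # per-head dim; defaults to d_model // n_heads

    def __post_init__(self) -> None:
        if self.d_k is None:
            self.d_k = self.d_model // self.n_heads
        if self.n_heads * self.d_k != self.d_model:
            raise ValueError("n_heads * d_k must equal d_model")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")

    def to_dict(self) -> dict:
        return {
            "d_model": self.d_model,
            "n_heads": self.n_heads,
            "d_ff": self.d_ff,
            "n_layers": self.n_layers,
            "dropout": self.dropout,
            "max_len": self.max_len,
            "seed": self.seed,
            "d_k": self.d_k,
        }


@dataclass
class AttentionParams:
    """Per-head Q/K/V projections stacked as (h, d_model, d_k), plus W_O."""

    W_Q: Tensor
    W_K: Tensor
    W_V: Tensor
    W_O: Tensor

    def tensors(self) -> list[Tensor]:
        return [self.W_Q, self.W_K, self.W_V, self.W_O]


@dataclass
class FFNParams:
    W1: Tensor
    b1: Tensor
    W2: Tensor
    b2: Tensor

    def tensors(self) -> list[Tensor]:
        return [self.W1, self.b1, self.W2, self.b2]


@dataclass
class LayerNormParams:
    gain: Tensor
    bias: Tensor
    eps: float = 1e-5

    def tensors(self) -> list[Tensor]:
        return [self.gain, self.bias]


@dataclass
class EncoderLayerParams:
    attn: AttentionParams
    ln1: LayerNormParams
    ffn: FFNParams
    ln2: LayerNormParams

    def tensors(self) -> list[Tensor]:
        return (
            self.attn.tensors() + self.ln1.tensors() + self.ffn.tensors() + self.ln2.tensors()
        )


@dataclass
class EncoderParams:
    embedding: Tensor
    layers: list[EncoderLayerParams] = field(default_factory=list)

    def tensors(self) -> list[Tensor]:
        out = [self.embedding]
        for layer in self.layers:
            out.extend(layer.tensors())
        return out


def init_attention_params(rng: np.random.Generator, d_model: int, n_heads: int, d_k: int) -> AttentionParams:
    # Q/K at 1/sqrt(fan-in) so attention logits are O(1) at init (a purely
    # 0.02-scale init leaves the softmax degenerate-uniform and attention
    # patterns never break symmetry); V/O stay small so the residual stream
    # is dominated by embeddings early in training.
    s = d_model**-0.5
    return AttentionParams(
        W_Q=parameter(rng, n_heads, d_model, d_k, scale=s),
        W_K=parameter(rng, n_heads, d_model, d_k, scale=s),
        W_V=parameter(rng, n_heads, d_model, d_k),
        W_O=parameter(rng, n_heads * d_k, d_model),
    )


def init_ffn_params(rng: np.random.Generator, d_model: int, d_ff: int) -> FFNParams:
    return FFNParams(
        W1=parameter(rng, d_model, d_ff),
        b1=Tensor(np.zeros(d_ff), requires_grad=True),
        W2=parameter(rng, d_ff, d_model),
        b2=Tensor(np.zeros(d_model), requires_grad=True),
    )


def init_layernorm_params(d_model: int, eps: float = 1e-5) -> LayerNormParams:
    return LayerNormParams(
        gain=Tensor(np.ones(d_model), requires_grad=True),
        bias=Tensor(np.zeros(d_model), requires_grad=True),
        eps=eps,
    )


def init_encoder_params(config: EncoderConfig, vocab_size: int) -> EncoderParams:
    """Seeded normal(0, 0.02) initialization; all randomness flows from
    `config.seed`."""
    rng = np.random.default_rng(config.seed)
    layers = [
        EncoderLayerParams(
            attn=init_attention_params(rng, config.d_model, config.n_heads, config.d_k),
            ln1=init_layernorm_params(config.d_model),
            ffn=init_ffn_params(rng, config.d_model, config.d_ff),
            ln2=init_layernorm_params(config.d_model),
        )
        for _ in range(config.n_layers)
    ]
    return EncoderParams(
        embedding=parameter(rng, vocab_size, config.d_model), layers=layers
    )


# ---------------------------------------------------------------------------
# functional building blocks (Tensor in, Tensor out; ndarray wrappers below)
# ---------------------------------------------------------------------------


def _wrap(x) -> tuple[Tensor, bool]:
    if isinstance(x, Tensor):
        return x, False
    return Tensor(np.asarray(x, dtype=np.float64)), True


def _mask_bias(mask: np.ndarray | None, shape: tuple[int, int]) -> np.ndarray | None:
    """Additive bias from a boolean mask marking *disallowed* key positions."""
    if mask is None:
        return None
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError(f"mask shape {mask.shape} does not match scores {shape}")
    if np.any(mask.all(axis=-1)):
        raise ValueError("softmax undefined: some query has every key masked")
    return np.where(mask, MASK_SENTINEL, 0.0)


def scaled_dot_attention(Q, K, V, mask: np.ndarray | None = None):
    """softmax(Q K^T / sqrt(d_k)) V; masked key positions get zero weight."""
    Qt, unwrap = _wrap(Q)
    Kt, _ = _wrap(K)
    Vt, _ = _wrap(V)
    d_k = Qt.shape[-1]
    scores = (Qt @ Kt.T) * (1.0 / np.sqrt(d_k))
    bias = _mask_bias(mask, (Qt.shape[0], Kt.shape[0]))
    weights = softmax(scores, axis=-1, bias=bias)
    out = weights @ Vt
    return out.data if unwrap else out


def attention_weights(Q, K, mask: np.ndarray | None = None) -> np.ndarray:
    """The normalized attention weight matrix alone (for invariant checks)."""
    Qt, _ = _wrap(Q)
    Kt, _ = _wrap(K)
    scores = (Qt @ Kt.T) * (1.0 / np.sqrt(Qt.shape[-1]))
    bias = _mask_bias(mask, (Qt.shape[0], Kt.shape[0]))
    return softmax(scores, axis=-1, bias=bias).data


def multi_head_attention(X, params: AttentionParams, mask: np.ndarray | None = None):
    """Concat of per-head scaled-dot attention outputs, projected by W_O."""
    Xt, unwrap = _wrap(X)
    n_heads = params.W_Q.shape[0]
    heads = []
    for h in range(n_heads):
        Qh = Xt @ params.W_Q[h]
        Kh = Xt @ params.W_K[h]
        Vh = Xt @ params.W_V[h]
        heads.append(scaled_dot_attention(Qh, Kh, Vh, mask=mask))
    out = concat(heads, axis=-1) @ params.W_O
    return out.data if unwrap else out


def cross_attention_block(X_q, X_kv, params: AttentionParams, mask: np.ndarray | None = None):
    """Multi-head attention with queries from one sequence and keys/values
    from another (the decoder-side cross-attention form)."""
    Qs, unwrap = _wrap(X_q)
    Ks, _ = _wrap(X_kv)
    n_heads = params.W_Q.shape[0]
    heads = []
    for h in range(n_heads):
        heads.append(
            scaled_dot_attention(
                Qs @ params.W_Q[h], Ks @ params.W_K[h], Ks @ params.W_V[h], mask=mask
            )
        )
    out = concat(heads, axis=-1) @ params.W_O
    return out.data if unwrap else out


def positional_encoding(pos: int, d_model: int) -> np.ndarray:
    """Sinusoidal position vector: even dims sin, odd dims cos."""
    if pos < 0:
        raise ValueError("position must be nonnegative")
    i = np.arange(d_model // 2 + d_model % 2)
    angle = pos / np.power(10000.0, 2.0 * i / d_model)
    vec = np.zeros(d_model)
    vec[0::2] = np.sin(angle)
    vec[1::2] = np.cos(angle[: d_model // 2])
    return vec


def positional_encoding_table(n_pos: int, d_model: int) -> np.ndarray:
    pos = np.arange(n_pos)[:, None]
    i = np.arange(d_model // 2 + d_model % 2)[None, :]
    angle = pos / np.power(10000.0, 2.0 * i / d_model)
    table = np.zeros((n_pos, d_model))
    table[:, 0::2] = np.sin(angle)
    table[:, 1::2] = np.cos(angle[:, : d_model // 2])
    return table


def ffn(X, params: FFNParams):
    """Position-wise feed-forward: max(0, x W1 + b1) W2 + b2."""
    Xt, unwrap = _wrap(X)
    out = (Xt @ params.W1 + params.b1).relu() @ params.W2 + params.b2
    return out.data if unwrap else out


def layer_norm(X, ln: LayerNormParams):
    Xt, unwrap = _wrap(X)
    mu = Xt.mean(axis=-1, keepdims=True)
    centered = Xt - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    normed = centered * (var + ln.eps).pow(-0.5)
    out = normed * ln.gain + ln.bias
    return out.data if unwrap else out


def residual_layernorm(X, sublayer_output, ln: LayerNormParams):
    """LayerNorm(x + Sublayer(x)) -- the post-norm residual wrapper."""
    Xt, unwrap = _wrap(X)
    St, _ = _wrap(sublayer_output)
    out = layer_norm(Xt + St, ln)
    return out.data if unwrap else out


def _dropout(x: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    if rate <= 0.0 or rng is None:
        return x
    keep = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(keep)


def embed_sequence(token_ids, config: EncoderConfig, params: EncoderParams) -> Tensor:
    ids = list(token_ids)
    if len(ids) > config.max_len:
        raise SequenceLengthError(
            f"sequence of {len(ids)} tokens exceeds max_len={config.max_len}"
        )
    emb = embedding(params.embedding, ids)
    return emb + Tensor(positional_encoding_table(len(ids), config.d_model))


def encoder_forward(
    token_ids,
    config: EncoderConfig,
    params: EncoderParams,
    train: bool = False,
    dropout_rng: np.random.Generator | None = None,
) -> Tensor:
    """Embeddings + positional encodings through the full layer stack.

    Deterministic in eval mode (`train=False`); dropout, when configured,
    is applied to each sublayer output before the residual add.
    """
    x = embed_sequence(token_ids, config, params)
    rng = dropout_rng if train else None
    for layer in params.layers:
        attn_out = multi_head_attention(x, layer.attn)
        x = residual_layernorm(x, _dropout(attn_out, config.dropout, rng), layer.ln1)
        ffn_out = ffn(x, layer.ffn)
        x = residual_layernorm(x, _dropout(ffn_out, config.dropout, rng), layer.ln2)
    return x
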