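"""Classification decoders over encoder outputs.

Two heads are implemented on top of the same encoder:

* **Slim decoder** -- a decoder block whose self-attention sublayer has been
  removed.  A single learned query position cross-attends over the encoder
  output (decoder-side Q, encoder-side K and V), passes through the
  feed-forward sublayer with residual + LayerNorm, and a linear + softmax
  layer scores the whole-label vocabulary.  One forward pass, one label:
  there is no input path for previously generated tokens, which is the
  non-autoregressive contract.

* **Autoregressive baseline** -- a minimal standard decoder block (causal
  self-attention + cross-attention + FFN) over a target vocabulary of
  whole-label tokens plus start/end symbols, trained with teacher forcing
  and decoded greedily left to right.

Labels are atomic vocabulary entries ("DDI-effect", "AGONIST"), never split
by the tokenizer, so a single decoding step suffices to emit one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, parameter, softmax
from .encoder import (
    AttentionParams,
    EncoderConfig,
    FFNParams,
    LayerNormParams,
    _wrap,
    cross_attention_block,
    ffn,
    init_attention_params,
    init_ffn_params,
    init_layernorm_params,
    multi_head_attention,
    positional_encoding_table,
    residual_layernorm,
)


@dataclass
class LabelVocabulary:
    """Ordered whole-label tokens with their embedding table and the learned
    query (start-token) embedding used at inference."""

    labels: list[str]
    embeddings: Tensor  # (n_labels + 2, d_model): labels then BOS then EOS
    query_index: int  # row used as the decoder query (the BOS row)

    @classmethod
    def create(cls, labels: list[str], d_model: int, rng: np.random.Generator) -> "LabelVocabulary":
        labels = list(labels)
        table = parameter(rng, len(labels) + 2, d_model)
        return cls(labels=labels, embeddings=table, query_index=len(labels))

    @property
    def bos_index(self) -> int:
        return len(self.labels)

    @property
    def eos_index(self) -> int:
        return len(self.labels) + 1

    def tensors(self) -> list[Tensor]:
        return [self.embeddings]


@dataclass
class DecoderBlockParams:
    """One decoder block; `self_attn` is None for the slim variant."""

    self_attn: AttentionParams | None
    ln_self: LayerNormParams | None
    cross: AttentionParams
    ln_cross: LayerNormParams
    ffn: FFNParams
    ln_ffn: LayerNormParams

    def tensors(self) -> list[Tensor]:
        out: list[Tensor] = []
        if self.self_attn is not None:
            out += self.self_attn.tensors() + self.ln_self.tensors()
        out += self.cross.tensors() + self.ln_cross.tensors()
        out += self.ffn.tensors() + self.ln_ffn.tensors()
        return out


def init_decoder_block(
    rng: np.random.Generator, config: EncoderConfig, with_self_attention: bool
) -> DecoderBlockParams:
    return DecoderBlockParams(
        self_attn=(
            init_attention_params(rng, config.d_model, config.n_heads, config.d_k)
            if with_self_attention
            else None
        ),
        ln_self=init_layernorm_params(config.d_model) if with_self_attention else None,
        cross=init_attention_params(rng, config.d_model, config.n_heads, config.d_k),
        ln_cross=init_layernorm_params(config.d_model),
        ffn=init_ffn_params(rng, config.d_model, config.d_ff),
        ln_ffn=init_layernorm_params(config.d_model),
    )


def cross_attention(query, encoder_out, params: AttentionParams):
    """Decoder-side queries attending over encoder keys/values (scaled
    dot-product form).

    Each output row is a convex combination of projected encoder rows.
    """
    qt, unwrap = _wrap(query)
    enc, _ = _wrap(encoder_out)
    if enc.shape[0] == 0:
        raise ValueError("encoder output is empty")
    squeeze = qt.ndim == 1
    if squeeze:
        qt = qt.reshape(1, -1)
    out = cross_attention_block(qt, enc, params)
    if squeeze:
        out = out.reshape(-1)
    return out.data if unwrap else out


def _decoder_block(
    x: Tensor,
    encoder_out: Tensor,
    params: DecoderBlockParams,
    causal_mask: np.ndarray | None,
) -> Tensor:
    if params.self_attn is not None:
        sa = multi_head_attention(x, params.self_attn, mask=causal_mask)
        x = residual_layernorm(x, sa, params.ln_self)
    ca = cross_attention_block(x, encoder_out, params.cross)
    x = residual_layernorm(x, ca, params.ln_cross)
    ff = ffn(x, params.ffn)
    return residual_layernorm(x, ff, params.ln_ffn)


@dataclass
class SlimDecoderParams:
    blocks: list[DecoderBlockParams]
    classifier_W: Tensor  # (d_model, n_labels)
    classifier_b: Tensor

    def tensors(self) -> list[Tensor]:
        out: list[Tensor] = []
        for b in self.blocks:
            out += b.tensors()
        return out + [self.classifier_W, self.classifier_b]


def init_slim_decoder(
    rng: np.random.Generator, config: EncoderConfig, n_labels: int, depth: int = 1
) -> SlimDecoderParams:
    return SlimDecoderParams(
        blocks=[init_decoder_block(rng, config, with_self_attention=False) for _ in range(depth)],
        classifier_W=parameter(rng, config.d_model, n_labels),
        classifier_b=Tensor(np.zeros(n_labels), requires_grad=True),
    )


def slim_decoder_logits(
    encoder_out, params: SlimDecoderParams, label_vocab: LabelVocabulary
) -> Tensor:
    """Raw label scores from a single learned query over the encoder output."""
    if not label_vocab.labels:
        raise ValueError("label vocabulary is empty")
    enc, _ = _wrap(encoder_out)
    query = label_vocab.embeddings[np.array([label_vocab.query_index])]
    x = query
    for block in params.blocks:
        x = _decoder_block(x, enc, block, causal_mask=None)
    return (x @ params.classifier_W + params.classifier_b).reshape(-1)


def slim_decoder_forward(
    encoder_out, params: SlimDecoderParams, label_vocab: LabelVocabulary
) -> np.ndarray:
    """Probability distribution over the whole-label vocabulary.

    Non-autoregressive: the computation has no input for previously
    generated tokens, so repeated calls are identical by construction.
    """
    logits = slim_decoder_logits(encoder_out, params, label_vocab)
    return softmax(logits, axis=-1).data


def classify(prob_vector: np.ndarray, labels: list[str]) -> str:
    """Argmax label; exact ties break toward the lowest label index."""
    p = np.asarray(prob_vector, dtype=np.float64)
    if np.any(np.isnan(p)):
        raise ValueError("NaN in probability vector")
    if len(p) != len(labels):
        raise ValueError("probability vector does not match label count")
    return labels[int(np.argmax(p))]


# ---------------------------------------------------------------------------
# autoregressive baseline
# ---------------------------------------------------------------------------


def causal_mask(n: int) -> np.ndarray:
    """True above the diagonal: position i may not attend to positions > i."""
    return np.triu(np.ones((n, n), dtype=bool), k=1)


@dataclass
class AutoregressiveDecoderParams:
    blocks: list[DecoderBlockParams]
    output_W: Tensor  # (d_model, n_labels + 2) over labels + BOS + EOS
    output_b: Tensor

    def tensors(self) -> list[Tensor]:
        out: list[Tensor] = []
        for b in self.blocks:
            out += b.tensors()
        return out + [self.output_W, self.output_b]


def init_autoregressive_decoder(
    rng: np.random.Generator, config: EncoderConfig, n_labels: int, depth: int = 1
) -> AutoregressiveDecoderParams:
    return AutoregressiveDecoderParams(
        blocks=[init_decoder_block(rng, config, with_self_attention=True) for _ in range(depth)],
        output_W=parameter(rng, config.d_model, n_labels + 2),
        output_b=Tensor(np.zeros(n_labels + 2), requires_grad=True),
    )


def decoder_step_logits(
    prefix_ids: list[int],
    encoder_out,
    params: AutoregressiveDecoderParams,
    label_vocab: LabelVocabulary,
    config: EncoderConfig,
) -> Tensor:
    """Logits for every prefix position (teacher-forcing form)."""
    enc, _ = _wrap(encoder_out)
    from .autodiff import embedding

    x = embedding(label_vocab.embeddings, prefix_ids)
    x = x + Tensor(positional_encoding_table(len(prefix_ids), config.d_model))
    mask = causal_mask(len(prefix_ids))
    for block in params.blocks:
        x = _decoder_block(x, enc, block, causal_mask=mask)
    return x @ params.output_W + params.output_b


def decode_autoregressive_baseline(
    encoder_out,
    params: AutoregressiveDecoderParams,
    label_vocab: LabelVocabulary,
    config: EncoderConfig,
    max_len: int = 4,
) -> tuple[list[int], bool]:
    """Greedy left-to-right generation until the end token or `max_len`.

    Returns (generated token ids excluding BOS/EOS, truncated flag); the
    truncated flag is set when no end token appeared within budget.
    """
    prefix = [label_vocab.bos_index]
    generated: list[int] = []
    for _ in range(max_len):
        logits = decoder_step_logits(prefix, encoder_out, params, label_vocab, config)
        nxt = int(np.argmax(logits.data[-1]))
        if nxt == label_vocab.eos_index:
            return generated, False
        generated.append(nxt)
        prefix.append(nxt)
    return generated, True
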