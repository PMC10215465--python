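"""Masked multi-head graph attention fused onto encoder hidden states.

The graph-attention (GAT) sublayer scores each edge (i, j) of a dependency
adjacency matrix with a single-layer feed-forward attention mechanism,

    e_ij = LeakyReLU(a^T [W h_i || W h_j]),   j in N_i,

normalizes the scores over each node's one-hop neighborhood (which always
contains the node itself, via self-loops), and aggregates the projected
neighbor features.  With K heads the default output is the averaged form
followed by a LeakyReLU; the concatenating form is available for ablation.
The sublayer is fused onto the encoder output with a residual connection
and LayerNorm: LayerNorm(x + GAT(x)).

Unlike scaled dot-product attention there is no sqrt(d) scaling here, and
attention is restricted to graph neighbors rather than the full sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, parameter
from .encoder import (
    MASK_SENTINEL,
    EncoderConfig,
    EncoderParams,
    LayerNormParams,
    _wrap,
    encoder_forward,
    init_layernorm_params,
    residual_layernorm,
)
from .autodiff import softmax


@dataclass
class GATConfig:
    n_heads: int = 2
    negative_slope: float = 0.2
    n_gat_layers: int = 1
    mode: str = "avg"  # "avg" (averaged heads) or "concat"
    head_dim: int | None = None  # concat mode only; defaults to d_model // K

    def __post_init__(self) -> None:
        if self.n_heads < 1:
            raise ValueError("K must be >= 1")
        if not 0.0 < self.negative_slope < 1.0:
            raise ValueError("negative_slope must lie in (0, 1)")
        if self.mode not in ("avg", "concat"):
            raise ValueError("mode must be 'avg' or 'concat'")

    def out_dim(self, d_model: int) -> int:
        if self.mode == "avg":
            return d_model
        head = self.head_dim or d_model // self.n_heads
        if head * self.n_heads != d_model:
            raise ValueError("concat mode requires K * head_dim == d_model")
        return head

    def to_dict(self) -> dict:
        return {
            "n_heads": self.n_heads,
            "negative_slope": self.negative_slope,
            "n_gat_layers": self.n_gat_layers,
            "mode": self.mode,
            "head_dim": self.head_dim,
        }


@dataclass
class GATLayerParams:
    """Per-head projection W^k, attention vector a^k, and the fused
    LayerNorm's gain/bias."""

    W: Tensor  # (K, d_model, d_out)
    a: Tensor  # (K, 2 * d_out)
    ln: LayerNormParams

    def tensors(self) -> list[Tensor]:
        return [self.W, self.a] + self.ln.tensors()


def init_gat_layer(
    rng: np.random.Generator, config: GATConfig, d_model: int
) -> GATLayerParams:
    d_out = config.out_dim(d_model)
    return GATLayerParams(
        W=parameter(rng, config.n_heads, d_model, d_out, scale=0.1),
        a=parameter(rng, config.n_heads, 2 * d_out, scale=0.1),
        ln=init_layernorm_params(d_model),
    )


def _check_dims(h_shape: tuple[int, ...], A: np.ndarray) -> None:
    if A.shape[0] != A.shape[1] or A.shape[0] != h_shape[0]:
        raise ValueError(
            f"adjacency {A.shape} does not match sequence length {h_shape[0]}"
        )


def gat_scores(h, params: GATLayerParams, A: np.ndarray, negative_slope: float = 0.2):
    """Per-head edge score matrices e^k.

    e_ij = LeakyReLU(a^T [W h_i || W h_j]) wherever A_ij = 1; non-neighbor
    entries carry a large negative sentinel so they drop out of the softmax.
    Returns a list of K matrices.
    """
    ht, unwrap = _wrap(h)
    A = np.asarray(A)
    _check_dims(ht.shape, A)
    n = A.shape[0]
    edge = Tensor(A.astype(np.float64))
    off = Tensor((1.0 - A) * MASK_SENTINEL)
    scores = []
    K = params.W.shape[0]
    d_out = params.W.shape[2]
    for k in range(K):
        Wh = ht @ params.W[k]  # (n, d_out)
        a_src = params.a[k][:d_out].reshape(d_out, 1)
        a_dst = params.a[k][d_out:].reshape(d_out, 1)
        s_i = (Wh @ a_src).reshape(n, 1)  # contribution of the query node i
        s_j = (Wh @ a_dst).reshape(1, n)  # contribution of the neighbor j
        e = (s_i + s_j).leaky_relu(negative_slope)
        scores.append(e * edge + off)
    return [s.data for s in scores] if unwrap else scores


def gat_attention(e, A: np.ndarray):
    """Neighborhood-masked softmax of the score matrices.

    alpha_ij >= 0, alpha_ij = 0 wherever A_ij = 0, and every row sums to 1
    over N_i (never empty thanks to self-loops).
    """
    A = np.asarray(A)
    assert np.all(np.diag(A) == 1), "self-loop invariant violated"
    single = not isinstance(e, (list, tuple))
    mats = [e] if single else list(e)
    out = []
    for mat in mats:
        t, unwrap = _wrap(mat)
        alpha = softmax(t, axis=-1)
        # zero any residual mass off the neighborhood (sentinel underflow)
        alpha = alpha * Tensor(A.astype(np.float64))
        alpha = alpha / alpha.sum(axis=-1, keepdims=True)
        out.append(alpha.data if unwrap else alpha)
    return out[0] if single else out


def gat_aggregate(alpha, h, params: GATLayerParams, config: GATConfig):
    """Head-wise neighborhood aggregation h'_i.

    avg mode:    LeakyReLU((1/K) sum_k sum_j alpha^k_ij W^k h_j)
    concat mode: ||_k ReLU(sum_j alpha^k_ij W^k h_j)
    """
    single = not isinstance(alpha, (list, tuple))
    alphas = [alpha] if single else list(alpha)
    ht, unwrap = _wrap(h)
    K = params.W.shape[0]
    if len(alphas) != K:
        raise ValueError(f"expected {K} coefficient matrices, got {len(alphas)}")
    per_head = []
    for k in range(K):
        ak, _ = _wrap(alphas[k])
        per_head.append(ak @ (ht @ params.W[k]))
    if config.mode == "avg":
        total = per_head[0]
        for t in per_head[1:]:
            total = total + t
        out = (total * (1.0 / K)).leaky_relu(config.negative_slope)
    else:
        out = concat([t.relu() for t in per_head], axis=-1)
    return out.data if unwrap else out


def gat_sublayer(x, A: np.ndarray, params: GATLayerParams, config: GATConfig):
    """Residual + LayerNorm around the scores -> softmax -> aggregate chain."""
    xt, unwrap = _wrap(x)
    e = gat_scores(xt, params, A, config.negative_slope)
    alpha = gat_attention(e, A)
    h_prime = gat_aggregate(alpha, xt, params, config)
    out = residual_layernorm(xt, h_prime, params.ln)
    return out.data if unwrap else out


# ---------------------------------------------------------------------------
# full classifier
# ---------------------------------------------------------------------------


@dataclass
class ClassifierHead:
    W: Tensor
    b: Tensor

    def tensors(self) -> list[Tensor]:
        return [self.W, self.b]


def _pool(x: Tensor, pooling: str, entity_spans=None) -> Tensor:
    """Sequence summary for classification.

    cls         -- the sequence-start token state
    mean        -- mean over all token states
    entity_pair -- concatenated means of the two target-entity spans (the
                   standard relation-classification head); requires spans
    """
    if pooling == "cls":
        return x[np.array([0])].reshape(-1)
    if pooling == "mean":
        return x.mean(axis=0)
    if pooling == "entity_pair":
        if not entity_spans or len(entity_spans) != 2:
            raise ValueError("entity_pair pooling requires two target spans")
        parts = []
        for span in entity_spans:
            idx = np.asarray(list(span), dtype=np.int64)
            parts.append(x[idx].mean(axis=0))
        return concat(parts, axis=-1)
    raise ValueError(f"unknown pooling {pooling!r}")


def head_input_dim(pooling: str, d_model: int) -> int:
    return 2 * d_model if pooling == "entity_pair" else d_model


class BertGATClassifier:
    """Transformer encoder + stacked GAT sublayers + linear softmax head.

    With `use_graph=False` (or an identity adjacency) the GAT sublayers see
    no cross-token edges: the no-graph ablation trained identically.
    """

    def __init__(
        self,
        config: EncoderConfig,
        gat_config: GATConfig,
        vocab_size: int,
        labels: list[str],
        pooling: str = "entity_pair",
        seed: int | None = None,
    ):
        self.config = config
        self.gat_config = gat_config
        self.labels = list(labels)
        self.pooling = pooling
        rng = np.random.default_rng(config.seed if seed is None else seed)
        # encoder params drawn from the same stream for full determinism
        from .encoder import (
            init_attention_params,
            init_ffn_params,
        )
        from .encoder import EncoderLayerParams

        self.encoder_params = EncoderParams(
            embedding=parameter(rng, vocab_size, config.d_model),
            layers=[
                EncoderLayerParams(
                    attn=init_attention_params(rng, config.d_model, config.n_heads, config.d_k),
                    ln1=init_layernorm_params(config.d_model),
                    ffn=init_ffn_params(rng, config.d_model, config.d_ff),
                    ln2=init_layernorm_params(config.d_model),
                )
                for _ in range(config.n_layers)
            ],
        )
        self.gat_layers = [
            init_gat_layer(rng, gat_config, config.d_model)
            for _ in range(gat_config.n_gat_layers)
        ]
        dim = head_input_dim(pooling, config.d_model)
        self.head = ClassifierHead(
            W=parameter(rng, dim, len(labels)), b=Tensor(np.zeros(len(labels)), requires_grad=True)
        )

    def parameters(self) -> list[Tensor]:
        out = self.encoder_params.tensors()
        for layer in self.gat_layers:
            out.extend(layer.tensors())
        out.extend(self.head.tensors())
        return out

    def logits(self, token_ids, A: np.ndarray, entity_spans=None, train: bool = False,
               dropout_rng=None) -> Tensor:
        x = encoder_forward(token_ids, self.config, self.encoder_params,
                            train=train, dropout_rng=dropout_rng)
        _check_dims(x.shape, np.asarray(A))
        for layer in self.gat_layers:
            x = gat_sublayer(x, A, layer, self.gat_config)
        pooled = _pool(x, self.pooling, entity_spans)
        return pooled.reshape(1, -1) @ self.head.W + self.head.b

    def predict_proba(self, token_ids, A: np.ndarray, entity_spans=None) -> np.ndarray:
        logits = self.logits(token_ids, A, entity_spans)
        return softmax(logits, axis=-1).data.reshape(-1)

    def predict(self, token_ids, A: np.ndarray, entity_spans=None) -> str:
        return self.labels[int(np.argmax(self.predict_proba(token_ids, A, entity_spans)))]


def bert_gat_classify(
    token_ids,
    A: np.ndarray,
    model: BertGATClassifier,
    entity_spans=None,
    instance_id: str | None = None,
) -> np.ndarray:
    """Probability distribution over the model's labels for one instance."""
    A = np.asarray(A)
    if A.shape[0] != len(list(token_ids)):
        raise ValueError(
            f"adjacency of size {A.shape[0]} does not align with "
            f"{len(list(token_ids))} tokens"
            + (f" (instance {instance_id})" if instance_id else "")
        )
    return model.predict_proba(token_ids, A, entity_spans)
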