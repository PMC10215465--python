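"""Model checkpoints: a directory of named weight arrays plus JSON metadata.

Layout::

    <dir>/config.json    encoder/GAT/training metadata and the model kind
    <dir>/vocab.json     tokenizer vocabulary
    <dir>/labels.json    ordered label list (the whole-label vocabulary)
    <dir>/weights.npz    parameter tensors, keyed p0000.. in parameters() order
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .encoder import EncoderConfig
from .gat import GATConfig
from .pipeline import AutoregressiveModel, GATRelationModel, SlimDecoderModel
from .vocab import Vocabulary

MODEL_KINDS = {
    "bert_gat": GATRelationModel,
    "bert_gat_ablation": GATRelationModel,
    "t5_slim_dec": SlimDecoderModel,
    "t5_autoregressive": AutoregressiveModel,
}


def model_kind(model) -> str:
    if isinstance(model, GATRelationModel):
        return "bert_gat" if model.use_graph else "bert_gat_ablation"
    if isinstance(model, SlimDecoderModel):
        return "t5_slim_dec"
    return "t5_autoregressive"


def save_model(model, vocab: Vocabulary, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    kind = model_kind(model)
    config = {
        "kind": kind,
        "encoder": model.config.to_dict(),
    }
    if isinstance(model, GATRelationModel):
        config["gat"] = model.gat_config.to_dict()
        config["pooling"] = model.net.pooling
    (out / "config.json").write_text(json.dumps(config, indent=2), encoding="utf-8")
    (out / "labels.json").write_text(json.dumps(model.labels), encoding="utf-8")
    vocab.save(out / "vocab.json")
    arrays = {f"p{i:04d}": t.data for i, t in enumerate(model.parameters())}
    np.savez(out / "weights.npz", **arrays)


def load_model(model_dir: str | Path):
    d = Path(model_dir)
    config = json.loads((d / "config.json").read_text(encoding="utf-8"))
    labels = json.loads((d / "labels.json").read_text(encoding="utf-8"))
    vocab = Vocabulary.load(d / "vocab.json")
    enc_cfg = EncoderConfig(**config["encoder"])
    kind = config["kind"]
    if kind in ("bert_gat", "bert_gat_ablation"):
        model = GATRelationModel(
            vocab,
            labels,
            config=enc_cfg,
            gat_config=GATConfig(**config["gat"]),
            use_graph=(kind == "bert_gat"),
            pooling=config.get("pooling", "entity_pair"),
        )
    elif kind == "t5_slim_dec":
        model = SlimDecoderModel(vocab, labels, config=enc_cfg)
    elif kind == "t5_autoregressive":
        model = AutoregressiveModel(vocab, labels, config=enc_cfg)
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    with np.load(d / "weights.npz") as payload:
        params = model.parameters()
        if len(payload.files) != len(params):
            raise ValueError("checkpoint does not match model parameterization")
        for i, t in enumerate(params):
            t.data = payload[f"p{i:04d}"]
    return model, vocab
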