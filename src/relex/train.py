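"""Seeded mini-batch training with AdamW and cross-entropy loss.

A model is anything exposing ``parameters() -> list[Tensor]``,
``loss(example) -> Tensor`` (scalar) and ``predict(example) -> str``.
Training shuffles with a generator derived from the config seed, accumulates
gradients over each mini-batch, and (when a held-out set is supplied) keeps
the parameter snapshot with the best held-out micro-F1 -- which for
single-label classification is plain accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np

from .autodiff import Tensor


class TrainableModel(Protocol):
    def parameters(self) -> list[Tensor]: ...

    def loss(self, example) -> Tensor: ...

    def predict(self, example) -> str: ...


@dataclass
class TrainConfig:
    learning_rate: float = 3e-3
    batch_size: int = 8
    epochs: int = 12
    weight_decay: float = 0.01
    warmup_steps: int = 100  # linear LR warmup; post-norm stacks need it
    seed: int = 0
    scheme: str = "DDI5"
    entity_masking: bool = True
    model: str = "bert_gat"

    def __post_init__(self) -> None:
        for name in ("learning_rate", "batch_size", "epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be nonnegative")


class AdamW:
    """Decoupled weight decay Adam over a list of parameter tensors."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, lr_scale: float = 1.0) -> None:
        self.t += 1
        lr = self.lr * lr_scale
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            p.data -= lr * (
                m_hat / (np.sqrt(v_hat) + self.eps) + self.weight_decay * p.data
            )


@dataclass
class TrainingLog:
    epoch_losses: list[float] = field(default_factory=list)
    val_accuracies: list[float] = field(default_factory=list)
    best_epoch: int | None = None
    best_val_accuracy: float | None = None


def accuracy_of(model: TrainableModel, examples: Sequence) -> float:
    if not examples:
        raise ValueError("cannot score an empty example set")
    correct = sum(model.predict(ex) == ex.label for ex in examples)
    return correct / len(examples)


def train(
    model: TrainableModel,
    examples: Sequence,
    config: TrainConfig,
    val_examples: Sequence | None = None,
) -> TrainingLog:
    """Optimize `model` in place; returns per-epoch losses (and, with a
    held-out set, restores the best-held-out-accuracy snapshot)."""
    if not examples:
        raise ValueError("cannot train on an empty instance set")
    params = model.parameters()
    opt = AdamW(
        params,
        lr=config.learning_rate,
        weight_decay=config.weight_decay,
    )
    rng = np.random.default_rng(config.seed)
    log = TrainingLog()
    best_state: list[np.ndarray] | None = None
    order = np.arange(len(examples))
    for epoch in range(config.epochs):
        rng.shuffle(order)
        total = 0.0
        for start in range(0, len(order), config.batch_size):
            batch = [examples[i] for i in order[start : start + config.batch_size]]
            opt.zero_grad()
            for ex in batch:
                loss = model.loss(ex)
                total += float(loss.data)
                loss.backward(np.asarray(1.0 / len(batch)))
            scale = min(1.0, (opt.t + 1) / config.warmup_steps) if config.warmup_steps else 1.0
            opt.step(lr_scale=scale)
        log.epoch_losses.append(total / len(order))
        if val_examples:
            acc = accuracy_of(model, val_examples)
            log.val_accuracies.append(acc)
            if log.best_val_accuracy is None or acc > log.best_val_accuracy:
                log.best_val_accuracy = acc
                log.best_epoch = epoch
                best_state = [p.data.copy() for p in params]
    if best_state is not None:
        for p, saved in zip(params, best_state):
            p.data = saved
    return log
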