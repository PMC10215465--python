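"""Multiclass evaluation: per-class precision/recall/F1, macro/micro/weighted
aggregation, and confusion matrices.

All quantities derive from per-class true-positive / false-positive /
false-negative counts.  In single-label classification over a fixed class
set, micro-averaged precision, recall and F1 all equal plain accuracy; the
reports produced here preserve that identity exactly.

Zero-denominator convention: a precision, recall or F1 whose denominator is
zero is reported as 0.0 (the convention used for classes with no correct
predictions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


def prf1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall and F1 from raw counts.

    F1 is the harmonic mean 2PR/(P+R); any zero denominator yields 0.0.
    """
    if tp < 0 or fp < 0 or fn < 0:
        raise ValueError("counts must be nonnegative")
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    if precision == recall:
        f1 = precision  # harmonic mean of equal values, kept exact
    elif precision + recall > 0:
        f1 = 2.0 * precision * recall / (precision + recall)
    else:
        f1 = 0.0
    return precision, recall, f1


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of an already-computed precision/recall pair."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class ClassRow:
    """Per-class slice of an evaluation report."""

    label: str
    precision: float
    recall: float
    f1: float
    support: int
    tp: int = 0
    fp: int = 0
    fn: int = 0


def aggregate(
    rows: Sequence[ClassRow], mode: str = "macro"
) -> tuple[float, float, float]:
    """Aggregate per-class rows into (precision, recall, F1).

    macro    -- unweighted mean over classes
    weighted -- support-weighted mean over classes
    micro    -- metrics of the pooled TP/FP/FN counts
    """
    if not rows:
        raise ValueError("cannot aggregate an empty row set")
    if mode == "macro":
        n = len(rows)
        return (
            sum(r.precision for r in rows) / n,
            sum(r.recall for r in rows) / n,
            sum(r.f1 for r in rows) / n,
        )
    if mode == "weighted":
        total = sum(r.support for r in rows)
        if total == 0:
            return 0.0, 0.0, 0.0
        return (
            sum(r.precision * r.support for r in rows) / total,
            sum(r.recall * r.support for r in rows) / total,
            sum(r.f1 * r.support for r in rows) / total,
        )
    if mode == "micro":
        tp = sum(r.tp for r in rows)
        fp = sum(r.fp for r in rows)
        fn = sum(r.fn for r in rows)
        return prf1(tp, fp, fn)
    raise ValueError(f"unknown aggregation mode: {mode!r}")


def confusion_matrix(
    gold: Sequence[str], predicted: Sequence[str], labels: Sequence[str]
) -> np.ndarray:
    """counts[g][p] over the ordered label list; trace == number correct."""
    if len(gold) != len(predicted):
        raise ValueError("gold and predicted must have equal length")
    index = {lab: i for i, lab in enumerate(labels)}
    mat = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for g, p in zip(gold, predicted):
        if g not in index:
            raise ValueError(f"gold label outside scheme: {g!r}")
        if p not in index:
            raise ValueError(f"predicted label outside scheme: {p!r}")
        mat[index[g], index[p]] += 1
    return mat


@dataclass
class EvaluationReport:
    """Full multiclass report: per-class rows, aggregates, confusion matrix."""

    labels: list[str]
    rows: list[ClassRow]
    accuracy: float
    macro: tuple[float, float, float]
    micro: tuple[float, float, float]
    weighted: tuple[float, float, float]
    confusion: np.ndarray
    n_instances: int
    positive_accuracy: float | None = None  # accuracy excluding gold negatives
    extras: dict = field(default_factory=dict)

    def row(self, label: str) -> ClassRow:
        for r in self.rows:
            if r.label == label:
                return r
        raise KeyError(label)

    def to_dict(self, ndigits: int = 4) -> dict:
        d = {
            "per_class": {
                r.label: {
                    "precision": round(r.precision, ndigits),
                    "recall": round(r.recall, ndigits),
                    "f1": round(r.f1, ndigits),
                    "support": r.support,
                }
                for r in self.rows
            },
            "accuracy": round(self.accuracy, ndigits),
            "macro": [round(v, ndigits) for v in self.macro],
            "micro": [round(v, ndigits) for v in self.micro],
            "weighted": [round(v, ndigits) for v in self.weighted],
            "n_instances": self.n_instances,
            "labels": self.labels,
            "confusion": self.confusion.tolist(),
        }
        if self.positive_accuracy is not None:
            d["positive_accuracy"] = round(self.positive_accuracy, ndigits)
        return d

    def to_tsv(self, ndigits: int = 4) -> str:
        """Per-class table in Precision / Recall / F1-Score / Support order."""
        lines = ["Relation Type\tPrecision\tRecall\tF1-Score\tSupport"]
        for r in self.rows:
            lines.append(
                f"{r.label}\t{round(r.precision, ndigits)}\t"
                f"{round(r.recall, ndigits)}\t{round(r.f1, ndigits)}\t{r.support}"
            )
        for name, agg in (
            ("Macro avg.", self.macro),
            ("Weighted avg.", self.weighted),
            ("Micro avg.", self.micro),
        ):
            p, rr, f = (round(v, ndigits) for v in agg)
            lines.append(f"{name}\t{p}\t{rr}\t{f}\t{self.n_instances}")
        lines.append(f"Accuracy\t\t\t{round(self.accuracy, ndigits)}\t{self.n_instances}")
        return "\n".join(lines) + "\n"


def evaluate(
    gold: Sequence[str],
    predicted: Sequence[str],
    labels: Sequence[str],
    negative_label: str | None = None,
) -> EvaluationReport:
    """Score predictions against gold labels over an ordered class set.

    When `negative_label` is given, `positive_accuracy` is additionally
    computed on the subset of instances whose gold label is not the
    negative class (the "-false" evaluation mode).
    """
    if len(gold) != len(predicted):
        raise ValueError("gold and predicted must have equal length")
    if not gold:
        raise ValueError("cannot evaluate an empty label sequence")
    mat = confusion_matrix(gold, predicted, labels)
    rows: list[ClassRow] = []
    for i, lab in enumerate(labels):
        tp = int(mat[i, i])
        fp = int(mat[:, i].sum() - tp)
        fn = int(mat[i, :].sum() - tp)
        p, r, f = prf1(tp, fp, fn)
        rows.append(ClassRow(lab, p, r, f, support=int(mat[i, :].sum()), tp=tp, fp=fp, fn=fn))
    n = len(gold)
    accuracy = float(np.trace(mat)) / n
    positive_accuracy = None
    if negative_label is not None:
        keep = [(g, p) for g, p in zip(gold, predicted) if g != negative_label]
        if keep:
            positive_accuracy = sum(g == p for g, p in keep) / len(keep)
    return EvaluationReport(
        labels=list(labels),
        rows=rows,
        accuracy=accuracy,
        macro=aggregate(rows, "macro"),
        micro=aggregate(rows, "micro"),
        weighted=aggregate(rows, "weighted"),
        confusion=mat,
        n_instances=n,
        positive_accuracy=positive_accuracy,
    )
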