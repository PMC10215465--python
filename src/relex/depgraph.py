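"""Dependency parses and the binary adjacency matrices they induce.

A dependency tree over n words becomes an n x n binary matrix A with
A_ij = 1 iff i == j (self-loop) or the words are linked by a dependency in
either direction; relation type labels are carried but deliberately ignored.
Because the downstream encoder operates on model (sub-word) tokens rather
than parse words, a word-level matrix can be projected onto model-token
positions through a :class:`TokenAlignment`: every sub-word inherits its
word's edges (expanded over the neighbor word's sub-words), sub-words of the
same word form a clique, and special tokens receive self-loops only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np


class ConlluParseError(ValueError):
    """Raised for malformed CoNLL-U content."""


class ParseValidationError(ValueError):
    """Raised when a parse violates the single-rooted-tree contract."""


@dataclass
class DependencyParse:
    """A single-rooted dependency tree in CoNLL-U head convention.

    `heads` are 1-based indices into `tokens`; 0 marks the root.
    `deprels` are carried for round-tripping but never interpreted.
    """

    tokens: list[str]
    heads: list[int]
    deprels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.deprels:
            self.deprels = ["dep"] * len(self.tokens)

    def validate(self) -> None:
        n = len(self.tokens)
        if len(self.heads) != n or len(self.deprels) != n:
            raise ParseValidationError("tokens, heads and deprels must align")
        roots = [i for i, h in enumerate(self.heads) if h == 0]
        if len(roots) != 1:
            raise ParseValidationError(
                f"expected exactly one root, found {len(roots)}"
            )
        for i, h in enumerate(self.heads):
            if not 0 <= h <= n:
                raise ParseValidationError(
                    f"token {i + 1}: head index {h} outside [0, {n}]"
                )

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class TokenAlignment:
    """Mapping from parse words to contiguous model-token index runs."""

    word_to_subwords: dict[int, list[int]]
    special_tokens: list[int] = field(default_factory=list)

    @property
    def n_model_tokens(self) -> int:
        covered = [i for run in self.word_to_subwords.values() for i in run]
        covered += list(self.special_tokens)
        return len(covered)

    def validate(self) -> None:
        covered = sorted(
            [i for run in self.word_to_subwords.values() for i in run]
            + list(self.special_tokens)
        )
        if covered != list(range(len(covered))):
            raise ValueError("alignment must cover all model-token positions exactly once")
        for w, run in self.word_to_subwords.items():
            if run != list(range(run[0], run[0] + len(run))):
                raise ValueError(f"word {w}: sub-word run must be contiguous")

    @classmethod
    def identity(cls, n_words: int) -> "TokenAlignment":
        return cls({i: [i] for i in range(n_words)})


def read_conllu(path: str | Path) -> list[DependencyParse]:
    """Read CoNLL-U sentence blocks (multiword ranges and empty nodes skipped)."""
    parses: list[DependencyParse] = []
    tokens: list[str] = []
    heads: list[int] = []
    deprels: list[str] = []

    def flush() -> None:
        nonlocal tokens, heads, deprels
        if tokens:
            parse = DependencyParse(tokens, heads, deprels)
            parse.validate()
            parses.append(parse)
        tokens, heads, deprels = [], [], []

    for ln, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.rstrip("\n")
        if not line.strip():
            flush()
            continue
        if line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 8:
            raise ConlluParseError(f"line {ln}: expected >= 8 tab-separated fields")
        tok_id = cols[0]
        if "-" in tok_id or "." in tok_id:  # multiword token range / empty node
            continue
        try:
            int(tok_id)
            head = int(cols[6])
        except ValueError:
            raise ConlluParseError(
                f"line {ln}: non-integer id or head field ({cols[0]!r}, {cols[6]!r})"
            ) from None
        tokens.append(cols[1])
        heads.append(head)
        deprels.append(cols[7])
    flush()
    return parses


def write_conllu(parses: Sequence[DependencyParse], path: str | Path) -> None:
    lines: list[str] = []
    for parse in parses:
        for i, (tok, head, rel) in enumerate(
            zip(parse.tokens, parse.heads, parse.deprels), 1
        ):
            lines.append(f"{i}\t{tok}\t_\t_\t_\t_\t{head}\t{rel}\t_\t_")
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def build_word_adjacency(parse: DependencyParse) -> np.ndarray:
    """Word-level adjacency: dependencies in both directions plus self-loops.

    The root's head-0 link creates no edge (there is no virtual root node).
    """
    parse.validate()
    n = len(parse)
    A = np.eye(n, dtype=np.int8)
    for child, head in enumerate(parse.heads):
        if head == 0:
            continue
        A[child, head - 1] = 1
        A[head - 1, child] = 1
    return A


def project_to_subwords(A_word: np.ndarray, alignment: TokenAlignment) -> np.ndarray:
    """Expand a word-level adjacency onto model-token positions.

    Every sub-word of word w inherits all of w's word edges (expanded over
    the neighbor word's sub-words), sub-words of the same word are fully
    interconnected, and special tokens get self-loops only.
    """
    alignment.validate()
    n_words = A_word.shape[0]
    covered = set(alignment.word_to_subwords)
    if covered != set(range(n_words)):
        raise ValueError(
            f"alignment covers words {sorted(covered)} but the adjacency has "
            f"{n_words} words"
        )
    n = alignment.n_model_tokens
    A = np.eye(n, dtype=np.int8)
    for w, run in alignment.word_to_subwords.items():
        for v in range(n_words):
            if A_word[w, v]:
                for i in run:
                    for j in alignment.word_to_subwords[v]:
                        A[i, j] = 1
                        A[j, i] = 1
        for i in run:
            for j in run:
                A[i, j] = 1
    return A


def neighbors(A: np.ndarray, i: int) -> list[int]:
    """Ascending one-hop neighborhood of node i, including i (self-loop)."""
    n = A.shape[0]
    if not 0 <= i < n:
        raise IndexError(f"node index {i} out of range for {n} nodes")
    return [int(j) for j in np.flatnonzero(A[i])]


def validate_adjacency(A: np.ndarray) -> None:
    """Assert the structural invariants every produced matrix must satisfy."""
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if not np.all(np.diag(A) == 1):
        raise ValueError("adjacency must have a unit diagonal")
    if not np.all((A == 0) | (A == 1)):
        raise ValueError("adjacency entries must be binary")


def adjacency_to_sparse(A: np.ndarray) -> dict:
    """Upper-triangle coordinate-list encoding for JSONL serialization."""
    ii, jj = np.nonzero(np.triu(A))
    return {"n": int(A.shape[0]), "edges": [[int(i), int(j)] for i, j in zip(ii, jj)]}


def adjacency_from_sparse(obj: dict) -> np.ndarray:
    A = np.zeros((obj["n"], obj["n"]), dtype=np.int8)
    for i, j in obj["edges"]:
        A[i, j] = 1
        A[j, i] = 1
    return A


def write_graphs(graphs: dict[str, np.ndarray], path: str | Path) -> None:
    """JSONL of {sentence_id, graph} objects for inspection and joining."""
    with open(path, "w", encoding="utf-8") as fh:
        for sid, A in graphs.items():
            fh.write(json.dumps({"sentence_id": sid, **adjacency_to_sparse(A)}) + "\n")


def read_graphs(path: str | Path) -> dict[str, np.ndarray]:
    graphs: dict[str, np.ndarray] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        obj = json.loads(line)
        graphs[obj["sentence_id"]] = adjacency_from_sparse(obj)
    return graphs
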