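"""Whitespace tokenizer with atomic reserved tokens and character fallback.

Tiny models trained from random initialization do not need a learned
sub-word vocabulary: words are whitespace tokens, a frequency cap bounds the
vocabulary, and out-of-vocabulary words fall back to their characters (so no
token is ever silently lost and sub-word/word alignment stays exercised).

Reserved *atomic* tokens -- sequence specials, entity-class placeholders,
pair separators, and whole-label tokens -- are always encoded as exactly one
id and are never split.  Label atomicity is what lets a classification
decoder treat "DDI-effect" or "AGONIST" as a single vocabulary entry.
"""

from __future__ import annotations

import json
from collections import Counter
from pathlib import Path
from typing import Iterable, Sequence

PAD = "[PAD]"
CLS = "[CLS]"
SEP = "[SEP]"
UNK = "[UNK]"
BOS = "<s>"
EOS = "</s>"

SPECIALS = (PAD, CLS, SEP, UNK, BOS, EOS)


class Vocabulary:
    def __init__(self, tokens: Sequence[str], atomic: Iterable[str] = ()):
        self._tokens = list(tokens)
        self._ids = {t: i for i, t in enumerate(self._tokens)}
        if len(self._ids) != len(self._tokens):
            raise ValueError("duplicate tokens in vocabulary")
        self._atomic = set(atomic) | set(SPECIALS)
        for t in SPECIALS:
            if t not in self._ids:
                raise ValueError(f"vocabulary must contain special token {t}")

    @classmethod
    def build(
        cls,
        texts: Iterable[str],
        atomic_tokens: Iterable[str] = (),
        max_size: int | None = None,
    ) -> "Vocabulary":
        """Build from whitespace-tokenized texts with a frequency cap.

        `atomic_tokens` (labels, class placeholders, separators) are always
        included and never split; the cap applies to ordinary words only.
        """
        atomic = list(dict.fromkeys(atomic_tokens))
        counts: Counter[str] = Counter()
        chars: set[str] = set()
        for text in texts:
            for word in text.split():
                counts[word] += 1
                chars.update(word)
        words = [w for w, _ in counts.most_common() if w not in atomic]
        if max_size is not None:
            words = words[:max_size]
        tokens = list(SPECIALS) + atomic + sorted(chars - set(atomic)) + [
            w for w in words if w not in SPECIALS and len(w) > 1
        ]
        # dedupe preserving order (single-char words already appear as chars)
        tokens = list(dict.fromkeys(tokens))
        return cls(tokens, atomic=atomic)

    def __len__(self) -> int:
        return len(self._tokens)

    def __contains__(self, token: str) -> bool:
        return token in self._ids

    def id_of(self, token: str) -> int:
        return self._ids[token]

    def token_of(self, idx: int) -> str:
        return self._tokens[idx]

    def is_atomic(self, token: str) -> bool:
        return token in self._atomic

    def encode_word(self, word: str) -> list[int]:
        """One id for known/atomic words; character fallback otherwise."""
        if word in self._ids:
            return [self._ids[word]]
        return [self._ids.get(ch, self._ids[UNK]) for ch in word]

    def encode_words(self, words: Sequence[str]) -> tuple[list[int], list[list[int]]]:
        """Encode a word sequence; also return per-word output positions."""
        ids: list[int] = []
        runs: list[list[int]] = []
        for word in words:
            piece = self.encode_word(word)
            runs.append(list(range(len(ids), len(ids) + len(piece))))
            ids.extend(piece)
        return ids, runs

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {"tokens": self._tokens, "atomic": sorted(self._atomic)}, ensure_ascii=False
        )

    @classmethod
    def from_json(cls, payload: str) -> "Vocabulary":
        obj = json.loads(payload)
        return cls(obj["tokens"], atomic=obj["atomic"])

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))
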