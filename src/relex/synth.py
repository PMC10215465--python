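"""Deterministic toy relation-extraction corpora with a planted structural
signal.

Each generated sentence is a chain of templated clauses over 2--4 entity
mentions:

* exactly one *pair clause* ``[subject-entity  verb  object-entity]`` placed
  at one end of the chain, whose verb is either a label-specific trigger
  word or a neutral transitive verb;
* zero or more *solo clauses* ``[entity  verb]`` with neutral intransitive
  verbs, conjoined by ``and`` tokens.

Clause verbs form a head chain (each verb depends on the previous clause's
verb), entities depend on their clause verb, so every sentence has a
projective single-rooted dependency tree.  The gold label of an entity pair
is, by construction, determined by the unique trigger word on the tree path
between the two entities -- the negative label if there is none.

With probability `off_path_distractor_rate` a *conflicting* trigger word is
attached as a leaf child of a clause verb, linearized directly before or
after it.  A leaf never lies on the path between two entities, so the gold
label remains recoverable from tree structure, while from the flat token
sequence the distractor is indistinguishable from a clause verb (the order
of the two adjacent trigger-type tokens is random).  This is what makes the
corpus a test bed for structure-aware models: a bag-of-words or purely
sequential reader faces irreducible ambiguity exactly where the
dependency graph disambiguates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

from .corpus import (
    DDI_NEGATIVE_LABEL,
    EntityClass,
    EntityMention,
    SchemeName,
    SentenceRecord,
    generate_instances,
    get_scheme,
    write_ddi_xml,
    write_instances,
)
from .depgraph import DependencyParse, write_conllu

#: default trigger lexicon: interaction label -> trigger verb
DDI_TRIGGERS = {
    "DDI-mechanism": "metabolizes",
    "DDI-effect": "potentiates",
    "DDI-advise": "contraindicates",
    "DDI-int": "interacts",
}

CPR_TRIGGERS = {
    "ACTIVATOR": "activates",
    "INHIBITOR": "inhibits",
    "AGONIST": "agonizes",
    "ANTAGONIST": "antagonizes",
    "SUBSTRATE": "metabolizes",
}

NEUTRAL_TRANSITIVE = ("accompanies", "precedes")
NEUTRAL_INTRANSITIVE = ("persists", "circulates", "dissolves")


class SyntheticSpecError(ValueError):
    pass


@dataclass
class SyntheticSpec:
    """Study conditions for one generated corpus."""

    n_sentences: int = 200
    entities_per_sentence: tuple[int, int] = (2, 4)
    style: str = "ddi"  # "ddi" or "cpr"
    trigger_lexicon: dict[str, str] = field(default_factory=lambda: dict(DDI_TRIGGERS))
    off_path_distractor_rate: float = 0.5
    trigger_rate: float = 0.6  # probability the pair clause carries a trigger verb
    seed: int = 0

    def __post_init__(self) -> None:
        if self.style == "cpr" and self.trigger_lexicon == DDI_TRIGGERS:
            self.trigger_lexicon = dict(CPR_TRIGGERS)
        labels = list(self.trigger_lexicon)
        triggers = list(self.trigger_lexicon.values())
        if len(set(triggers)) != len(triggers):
            raise SyntheticSpecError("trigger lexicon must be injective")
        if self.style == "ddi":
            scheme_labels = set(get_scheme(SchemeName.DDI4).labels)
            if not scheme_labels <= set(labels):
                raise SyntheticSpecError(
                    "trigger lexicon must cover every positive label of the scheme"
                )
        if not 0.0 <= self.off_path_distractor_rate <= 1.0:
            raise SyntheticSpecError("distractor rate must lie in [0, 1]")
        lo, hi = self.entities_per_sentence
        if not 2 <= lo <= hi:
            raise SyntheticSpecError("entities per sentence must be >= 2")

    @property
    def negative_label(self) -> str:
        return DDI_NEGATIVE_LABEL if self.style == "ddi" else "CPR-false"


@dataclass
class SyntheticSentence:
    record: SentenceRecord
    parse: DependencyParse
    entity_word: dict[str, int]  # mention id -> 0-based word index


@dataclass
class SyntheticCorpus:
    spec: SyntheticSpec
    sentences: list[SyntheticSentence]

    @property
    def records(self) -> list[SentenceRecord]:
        return [s.record for s in self.sentences]

    @property
    def parses(self) -> dict[str, DependencyParse]:
        return {s.record.id: s.parse for s in self.sentences}


def tree_path(parse: DependencyParse, a: int, b: int) -> list[int]:
    """0-based word indices on the tree path from a to b, inclusive."""
    parse.validate()

    def ancestors(i: int) -> list[int]:
        chain = [i]
        while parse.heads[chain[-1]] != 0:
            chain.append(parse.heads[chain[-1]] - 1)
        return chain

    up_a, up_b = ancestors(a), ancestors(b)
    set_b = {n: k for k, n in enumerate(up_b)}
    for k, node in enumerate(up_a):
        if node in set_b:
            return up_a[: k + 1] + up_b[: set_b[node]][::-1]
    raise AssertionError("tree is connected; a common ancestor must exist")


def oracle_label(
    parse: DependencyParse,
    pair: tuple[int, int],
    lexicon: dict[str, str],
    negative_label: str = DDI_NEGATIVE_LABEL,
) -> str:
    """Label read from the unique on-path trigger word; negative if absent.

    Two triggers on one path indicate a generation bug and trip an
    assertion.
    """
    inverse = {v: k for k, v in lexicon.items()}
    hits = [
        inverse[parse.tokens[i]]
        for i in tree_path(parse, pair[0], pair[1])
        if parse.tokens[i] in inverse
    ]
    assert len(hits) <= 1, f"two triggers on one path: {hits}"
    return hits[0] if hits else negative_label


def word_index_of_char(text: str, char_start: int) -> int:
    """Index of the whitespace token starting at `char_start`."""
    return text[:char_start].count(" ")


def _entity_name(rng: np.random.Generator, style: str, eclass: EntityClass) -> str:
    letter = chr(ord("A") + int(rng.integers(26)))
    num = int(rng.integers(100))
    if style == "ddi":
        return f"drug{letter}{num}"
    return (f"chem{letter}{num}" if eclass == EntityClass.CHEMICAL else f"prot{letter}{num}")


def _generate_sentence(
    rng: np.random.Generator, spec: SyntheticSpec, sid: str
) -> SyntheticSentence:
    lo, hi = spec.entities_per_sentence
    m = int(rng.integers(lo, hi + 1))
    labels = sorted(spec.trigger_lexicon)

    if spec.style == "ddi":
        classes = [EntityClass.DRUG] * m
    else:
        # the pair clause holds a chemical subject and a protein object
        classes = [EntityClass.CHEMICAL, EntityClass.GENE_PROTEIN] + [
            (EntityClass.CHEMICAL if i % 2 == 0 else EntityClass.GENE_PROTEIN)
            for i in range(m - 2)
        ]
    names: list[str] = []
    for eclass in classes:
        name = _entity_name(rng, spec.style, eclass)
        while name in names:
            name = _entity_name(rng, spec.style, eclass)
        names.append(name)

    has_trigger = rng.random() < spec.trigger_rate
    trigger_label = labels[int(rng.integers(len(labels)))] if has_trigger else None
    pair_verb = (
        spec.trigger_lexicon[trigger_label]
        if trigger_label
        else NEUTRAL_TRANSITIVE[int(rng.integers(len(NEUTRAL_TRANSITIVE)))]
    )

    # clause plan: one pair clause at a chain end, solo clauses for the rest
    n_solo = m - 2
    pair_first = bool(rng.random() < 0.5) or n_solo == 0
    clause_kinds = (["pair"] + ["solo"] * n_solo) if pair_first else (["solo"] * n_solo + ["pair"])

    has_distractor = rng.random() < spec.off_path_distractor_rate
    distractor_word = None
    if has_distractor:
        candidates = [l for l in labels if l != trigger_label]
        distractor_word = spec.trigger_lexicon[candidates[int(rng.integers(len(candidates)))]]
        distractor_clause = int(rng.integers(len(clause_kinds)))
        distractor_before_verb = bool(rng.random() < 0.5)

    tokens: list[str] = []
    heads: list[int] = []
    deprels: list[str] = []
    entity_word: dict[str, int] = {}
    entity_order: list[tuple[str, EntityClass, int]] = []  # (name, class, word idx)
    prev_verb_1b = 0  # 1-based head for the chain; 0 = root
    next_entity = 0

    def emit(tok: str, head_1b: int, rel: str) -> int:
        tokens.append(tok)
        heads.append(head_1b)
        deprels.append(rel)
        return len(tokens)  # 1-based index of the emitted token

    for c_idx, kind in enumerate(clause_kinds):
        if c_idx > 0:
            and_pos = len(tokens)  # patched to the clause verb below
            emit("and", -1, "cc")
        if kind == "pair":
            subj_i, obj_i = next_entity, next_entity + 1
            next_entity += 2
            subj_pos = emit(names[subj_i], -1, "nsubj")
            verb_parts: list[tuple[str, str]] = [(pair_verb, "verb")]
            if has_distractor and distractor_clause == c_idx:
                verb_parts.insert(0 if distractor_before_verb else 1, (distractor_word, "dep"))
            verb_1b = None
            distr_pos = []
            for word, role in verb_parts:
                pos = emit(word, -1, role)
                if role == "verb":
                    verb_1b = pos
                else:
                    distr_pos.append(pos)
            obj_pos = emit(names[obj_i], verb_1b, "obj")
            heads[subj_pos - 1] = verb_1b
            for p in distr_pos:
                heads[p - 1] = verb_1b
            for i, pos in ((subj_i, subj_pos), (obj_i, obj_pos)):
                entity_order.append((names[i], classes[i], pos - 1))
        else:
            ent_i = next_entity
            next_entity += 1
            ent_pos = emit(names[ent_i], -1, "nsubj")
            solo_verb = NEUTRAL_INTRANSITIVE[int(rng.integers(len(NEUTRAL_INTRANSITIVE)))]
            verb_parts = [(solo_verb, "verb")]
            if has_distractor and distractor_clause == c_idx:
                verb_parts.insert(0 if distractor_before_verb else 1, (distractor_word, "dep"))
            verb_1b = None
            distr_pos = []
            for word, role in verb_parts:
                pos = emit(word, -1, role)
                if role == "verb":
                    verb_1b = pos
                else:
                    distr_pos.append(pos)
            heads[ent_pos - 1] = verb_1b
            for p in distr_pos:
                heads[p - 1] = verb_1b
            entity_order.append((names[ent_i], classes[ent_i], ent_pos - 1))
        # chain attachment and conjunction head
        heads[verb_1b - 1] = prev_verb_1b
        deprels[verb_1b - 1] = "root" if prev_verb_1b == 0 else "conj"
        if c_idx > 0:
            heads[and_pos] = verb_1b
        prev_verb_1b = verb_1b

    parse = DependencyParse(tokens, heads, deprels)
    parse.validate()

    text = " ".join(tokens)
    mentions: list[EntityMention] = []
    offsets = np.cumsum([0] + [len(t) + 1 for t in tokens])
    for k, (name, eclass, widx) in enumerate(sorted(entity_order, key=lambda x: x[2])):
        mid = f"{sid}.e{k}"
        mentions.append(
            EntityMention(
                id=mid,
                entity_class=eclass,
                char_start=int(offsets[widx]),
                char_end=int(offsets[widx]) + len(name),
                surface_text=name,
            )
        )
        entity_word[mid] = widx

    gold: set[tuple[str, str, str]] = set()
    for m1, m2 in combinations(mentions, 2):
        if spec.style == "cpr" and m1.entity_class == m2.entity_class:
            continue
        label = oracle_label(
            parse,
            (entity_word[m1.id], entity_word[m2.id]),
            spec.trigger_lexicon,
            negative_label=spec.negative_label,
        )
        if label != spec.negative_label:
            gold.add((m1.id, m2.id, label))

    record = SentenceRecord(id=sid, text=text, mentions=mentions, gold_relations=gold)
    record.validate()
    return SyntheticSentence(record=record, parse=parse, entity_word=entity_word)


def generate_corpus(spec: SyntheticSpec, out_dir: str | Path | None = None) -> SyntheticCorpus:
    """Generate a corpus; optionally emit corpus.xml / corpus.conllu /
    instances.jsonl under `out_dir`.  Fully deterministic given spec.seed."""
    rng = np.random.default_rng(spec.seed)
    sentences = [
        _generate_sentence(rng, spec, f"synth.s{i}") for i in range(spec.n_sentences)
    ]
    corpus = SyntheticCorpus(spec=spec, sentences=sentences)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if spec.style == "ddi":
            write_ddi_xml(corpus.records, out / "corpus.xml")
            scheme = get_scheme(SchemeName.DDI5)
        else:
            scheme = get_scheme(SchemeName.CPR_FINE)
        write_conllu([s.parse for s in sentences], out / "corpus.conllu")
        instances = [
            inst
            for rec in corpus.records
            for inst in generate_instances(rec, scheme, mask_entities=True)
        ]
        write_instances(instances, out / "instances.jsonl")
    return corpus
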