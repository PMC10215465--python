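"""Corpus model for sentence-level biomedical relation extraction.

Two corpus families are supported:

* drug--drug interaction (DDI) corpora distributed as per-sentence XML, where
  every drug pair in a sentence is a candidate and unannotated pairs count as
  the negative class ``DDI-false``;
* chemical--protein relation (CPR) corpora distributed as TSV triplets
  (abstracts / entities / relations), where only annotated chemical--protein
  pairs form instances and fine-grained relation types group into CPR classes.

A classification instance is one candidate entity pair in one sentence: the
sentence text with the two target mentions wrapped in separator tokens
(``**`` for drugs and genes/proteins, ``##`` for chemicals), optionally with
every entity mention masked by its class placeholder (``@DRUG$``, ``@CHEM$``,
``@PROT$``) so models must classify from context rather than lexical identity.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

from lxml import etree

logger = logging.getLogger(__name__)


class CorpusParseError(ValueError):
    """Raised when an input file cannot be parsed at all."""


class CorpusValidationError(ValueError):
    """Raised when parsed content violates a corpus invariant."""


class SchemeMismatchError(ValueError):
    """Raised when a label scheme is applied to an incompatible record."""


class EntityClass(str, Enum):
    DRUG = "DRUG"
    CHEMICAL = "CHEMICAL"
    GENE_PROTEIN = "GENE_PROTEIN"


#: entity-class masking placeholders
CLASS_TOKENS = {
    EntityClass.DRUG: "@DRUG$",
    EntityClass.CHEMICAL: "@CHEM$",
    EntityClass.GENE_PROTEIN: "@PROT$",
}

#: pair-marking separator per entity class; the chemical mention of a
#: chemical--protein pair is wrapped with ``##``, everything else with ``**``
SEPARATORS = {
    EntityClass.DRUG: "**",
    EntityClass.CHEMICAL: "##",
    EntityClass.GENE_PROTEIN: "**",
}


@dataclass(frozen=True)
class EntityMention:
    """An annotated entity span; offsets are 0-based, end-exclusive."""

    id: str
    entity_class: EntityClass
    char_start: int
    char_end: int
    surface_text: str

    def validate(self, sentence_text: str) -> None:
        if not (0 <= self.char_start < self.char_end <= len(sentence_text)):
            raise CorpusValidationError(
                f"mention {self.id}: offsets [{self.char_start}, {self.char_end}) "
                f"outside sentence of length {len(sentence_text)}"
            )
        actual = sentence_text[self.char_start : self.char_end]
        if actual != self.surface_text:
            raise CorpusValidationError(
                f"mention {self.id}: surface {self.surface_text!r} does not match "
                f"text slice {actual!r}"
            )


@dataclass
class SentenceRecord:
    """One sentence with its entity mentions and gold pairwise relations."""

    id: str
    text: str
    mentions: list[EntityMention] = field(default_factory=list)
    gold_relations: set[tuple[str, str, str]] = field(default_factory=set)

    def validate(self) -> None:
        ids = [m.id for m in self.mentions]
        if len(ids) != len(set(ids)):
            raise CorpusValidationError(f"sentence {self.id}: duplicate mention ids")
        for m in self.mentions:
            try:
                m.validate(self.text)
            except CorpusValidationError as exc:
                raise CorpusValidationError(f"sentence {self.id}: {exc}") from exc
        known = set(ids)
        for e1, e2, label in self.gold_relations:
            if e1 == e2:
                raise CorpusValidationError(
                    f"sentence {self.id}: relation {label} pairs {e1} with itself"
                )
            if e1 not in known or e2 not in known:
                raise CorpusValidationError(
                    f"sentence {self.id}: relation {label} references unknown "
                    f"mention ({e1}, {e2})"
                )

    def mention(self, mention_id: str) -> EntityMention:
        for m in self.mentions:
            if m.id == mention_id:
                return m
        raise KeyError(mention_id)


class SchemeName(str, Enum):
    DDI5 = "DDI5"
    DDI4 = "DDI4"
    CPR_GROUP = "CPR_GROUP"
    CPR_FINE = "CPR_FINE"


@dataclass(frozen=True)
class LabelScheme:
    """An ordered label set with an optional designated negative class."""

    name: SchemeName
    labels: tuple[str, ...]
    negative_label: str | None = None

    def __post_init__(self) -> None:
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("scheme labels must be unique")
        if self.negative_label is not None and self.negative_label not in self.labels:
            raise ValueError("negative label must belong to the label set")


@dataclass(frozen=True)
class RelationInstance:
    """One candidate entity pair: the unit of classification."""

    sentence_id: str
    pair: tuple[str, str]
    marked_text: str
    label: str
    scheme: SchemeName


DDI_POSITIVE_LABELS = ("DDI-advise", "DDI-effect", "DDI-int", "DDI-mechanism")
DDI_NEGATIVE_LABEL = "DDI-false"

#: fine relation type -> owning CPR class group (all annotated groups)
CPR_GROUP_OF = {
    "UNDEFINED": "CPR:0",
    "PART-OF": "CPR:1",
    "DIRECT-REGULATOR": "CPR:2",
    "INDIRECT-REGULATOR": "CPR:2",
    "REGULATOR": "CPR:2",
    "ACTIVATOR": "CPR:3",
    "INDIRECT-UPREGULATOR": "CPR:3",
    "UPREGULATOR": "CPR:3",
    "DOWNREGULATOR": "CPR:4",
    "INDIRECT-DOWNREGULATOR": "CPR:4",
    "INHIBITOR": "CPR:4",
    "AGONIST": "CPR:5",
    "AGONIST-ACTIVATOR": "CPR:5",
    "AGONIST-INHIBITOR": "CPR:5",
    "ANTAGONIST": "CPR:6",
    "MODULATOR": "CPR:7",
    "MODULATOR-ACTIVATOR": "CPR:7",
    "MODULATOR-INHIBITOR": "CPR:7",
    "COFACTOR": "CPR:8",
    "SUBSTRATE": "CPR:9",
    "SUBSTRATE_PRODUCT-OF": "CPR:9",
    "PRODUCT-OF": "CPR:9",
    "NOT": "CPR:10",
}

#: the five CPR class groups designated for evaluation
CPR_EVAL_GROUPS = ("CPR:3", "CPR:4", "CPR:5", "CPR:6", "CPR:9")

#: the 13 fine relation types belonging to the evaluated groups, group order
CPR_FINE_LABELS = tuple(
    fine
    for group in CPR_EVAL_GROUPS
    for fine in sorted(f for f, g in CPR_GROUP_OF.items() if g == group)
)

SCHEMES: dict[SchemeName, LabelScheme] = {
    SchemeName.DDI4: LabelScheme(SchemeName.DDI4, DDI_POSITIVE_LABELS),
    SchemeName.DDI5: LabelScheme(
        SchemeName.DDI5,
        DDI_POSITIVE_LABELS + (DDI_NEGATIVE_LABEL,),
        negative_label=DDI_NEGATIVE_LABEL,
    ),
    SchemeName.CPR_GROUP: LabelScheme(SchemeName.CPR_GROUP, CPR_EVAL_GROUPS),
    SchemeName.CPR_FINE: LabelScheme(SchemeName.CPR_FINE, CPR_FINE_LABELS),
}


def get_scheme(name: str | SchemeName) -> LabelScheme:
    return SCHEMES[SchemeName(name)]


def map_cpr_group(fine_type: str) -> str:
    """Map a fine chemical--protein relation type to its CPR class group."""
    try:
        return CPR_GROUP_OF[fine_type]
    except KeyError:
        valid = ", ".join(sorted(CPR_GROUP_OF))
        raise LookupError(
            f"unknown relation type {fine_type!r}; valid types: {valid}"
        ) from None


# ---------------------------------------------------------------------------
# overlap resolution and masking
# ---------------------------------------------------------------------------


def resolve_overlaps(mentions: Sequence[EntityMention]) -> list[EntityMention]:
    """Drop the shorter of any two overlapping mentions, with a warning."""
    kept: list[EntityMention] = []
    for m in sorted(mentions, key=lambda x: (x.char_start, -(x.char_end - x.char_start))):
        clash = next(
            (k for k in kept if m.char_start < k.char_end and k.char_start < m.char_end),
            None,
        )
        if clash is None:
            kept.append(m)
        else:
            shorter = m  # sort order guarantees the later one is not longer
            logger.warning(
                "overlapping mentions %s and %s; dropping shorter %s",
                clash.id,
                m.id,
                shorter.id,
            )
    return sorted(kept, key=lambda x: x.char_start)


def mask_record(record: SentenceRecord) -> SentenceRecord:
    """Replace every mention's surface form by its entity-class token.

    Idempotent: masking an already-masked record returns an equal record.
    Offsets are rewritten so the result is again a valid record.
    """
    record.validate()
    mentions = sorted(record.mentions, key=lambda m: m.char_start)
    pieces: list[str] = []
    new_mentions: list[EntityMention] = []
    cursor = 0
    out_len = 0
    for m in mentions:
        gap = record.text[cursor : m.char_start]
        pieces.append(gap)
        out_len += len(gap)
        token = CLASS_TOKENS[m.entity_class]
        new_mentions.append(
            replace(m, char_start=out_len, char_end=out_len + len(token), surface_text=token)
        )
        pieces.append(token)
        out_len += len(token)
        cursor = m.char_end
    pieces.append(record.text[cursor:])
    return SentenceRecord(
        id=record.id,
        text="".join(pieces),
        mentions=new_mentions,
        gold_relations=set(record.gold_relations),
    )


# ---------------------------------------------------------------------------
# instance generation
# ---------------------------------------------------------------------------


def _build_marked_text(
    record: SentenceRecord,
    target_ids: tuple[str, str],
    mask_entities: bool,
) -> str:
    """Wrap the two target mentions in separators; optionally mask all
    mentions with their class tokens.  Replacements proceed right-to-left
    by char_start so earlier offsets stay valid."""
    text = record.text
    for m in sorted(record.mentions, key=lambda x: x.char_start, reverse=True):
        repl = CLASS_TOKENS[m.entity_class] if mask_entities else m.surface_text
        if m.id in target_ids:
            sep = SEPARATORS[m.entity_class]
            repl = f"{sep} {repl} {sep}"
        elif not mask_entities:
            continue
        text = text[: m.char_start] + repl + text[m.char_end :]
    return text


def generate_instances(
    record: SentenceRecord,
    scheme: LabelScheme,
    mask_entities: bool = False,
) -> list[RelationInstance]:
    """Produce the candidate-pair classification instances of one sentence.

    DDI schemes enumerate every unordered drug pair; a pair without a gold
    relation is ``DDI-false``, and the 4-class scheme drops those.  CPR
    schemes produce one instance per gold chemical--protein relation whose
    (optionally group-mapped) label lies in the scheme's label set.
    """
    record.validate()
    classes = {m.entity_class for m in record.mentions}
    if scheme.name in (SchemeName.DDI4, SchemeName.DDI5):
        if classes - {EntityClass.DRUG}:
            raise SchemeMismatchError(
                f"sentence {record.id}: DDI scheme applied to a record with "
                f"non-drug mentions {sorted(c.value for c in classes)}"
            )
        return _generate_ddi(record, scheme, mask_entities)
    if classes - {EntityClass.CHEMICAL, EntityClass.GENE_PROTEIN}:
        raise SchemeMismatchError(
            f"sentence {record.id}: CPR scheme applied to a record with "
            f"mention classes {sorted(c.value for c in classes)}"
        )
    return _generate_cpr(record, scheme, mask_entities)


def _gold_lookup(record: SentenceRecord) -> dict[frozenset, str]:
    gold: dict[frozenset, str] = {}
    for e1, e2, label in record.gold_relations:
        gold[frozenset((e1, e2))] = label
    return gold


def _generate_ddi(
    record: SentenceRecord, scheme: LabelScheme, mask_entities: bool
) -> list[RelationInstance]:
    gold = _gold_lookup(record)
    instances = []
    for m1, m2 in combinations(record.mentions, 2):
        label = gold.get(frozenset((m1.id, m2.id)), DDI_NEGATIVE_LABEL)
        if label not in scheme.labels:
            if label == DDI_NEGATIVE_LABEL and scheme.name == SchemeName.DDI4:
                continue
            raise CorpusValidationError(
                f"sentence {record.id}: gold label {label!r} outside scheme "
                f"{scheme.name.value}"
            )
        instances.append(
            RelationInstance(
                sentence_id=record.id,
                pair=(m1.id, m2.id),
                marked_text=_build_marked_text(record, (m1.id, m2.id), mask_entities),
                label=label,
                scheme=scheme.name,
            )
        )
    return instances


def _generate_cpr(
    record: SentenceRecord, scheme: LabelScheme, mask_entities: bool
) -> list[RelationInstance]:
    instances = []
    for e1, e2, fine in sorted(record.gold_relations):
        label = map_cpr_group(fine) if scheme.name == SchemeName.CPR_GROUP else fine
        if label not in scheme.labels:
            continue
        instances.append(
            RelationInstance(
                sentence_id=record.id,
                pair=(e1, e2),
                marked_text=_build_marked_text(record, (e1, e2), mask_entities),
                label=label,
                scheme=scheme.name,
            )
        )
    return instances


# ---------------------------------------------------------------------------
# DDI-style XML
# ---------------------------------------------------------------------------

_DDI_LABEL_PREFIX = "DDI-"


def _normalize_ddi_label(raw: str) -> str:
    return raw if raw.startswith(_DDI_LABEL_PREFIX) else _DDI_LABEL_PREFIX + raw


def read_ddi_xml(path: str | Path) -> list[SentenceRecord]:
    """Read a DDI-2013-style XML document of sentence/entity/pair elements.

    ``charOffset`` attributes use the corpus convention of inclusive end
    offsets; they are converted to 0-based end-exclusive internally.
    Discontinuous (multi-span) mentions are dropped with a warning.
    Pairs with ``ddi="true"`` become gold relations; other drug pairs are
    implicitly ``DDI-false`` (materialized later by instance generation).
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise CorpusParseError(f"{path.name}: malformed XML: {exc}") from exc
    records: list[SentenceRecord] = []
    for sent in tree.getroot().iter("sentence"):
        sid = sent.get("id", f"s{len(records)}")
        text = sent.get("text", "")
        mentions: list[EntityMention] = []
        for ent in sent.iter("entity"):
            offset = ent.get("charOffset", "")
            if ";" in offset:
                logger.warning(
                    "sentence %s: discontinuous entity %s dropped", sid, ent.get("id")
                )
                continue
            try:
                start_s, end_s = offset.split("-")
                start, end = int(start_s), int(end_s) + 1
            except ValueError:
                raise CorpusParseError(
                    f"sentence {sid}: entity {ent.get('id')} has malformed "
                    f"charOffset {offset!r}"
                ) from None
            mentions.append(
                EntityMention(
                    id=ent.get("id"),
                    entity_class=EntityClass.DRUG,
                    char_start=start,
                    char_end=end,
                    surface_text=ent.get("text", ""),
                )
            )
        mentions = resolve_overlaps(mentions)
        kept_ids = {m.id for m in mentions}
        gold: set[tuple[str, str, str]] = set()
        for pair in sent.iter("pair"):
            if pair.get("ddi", "false").lower() != "true":
                continue
            e1, e2 = pair.get("e1"), pair.get("e2")
            if e1 not in kept_ids or e2 not in kept_ids:
                logger.warning(
                    "sentence %s: pair %s references dropped entity", sid, pair.get("id")
                )
                continue
            label = _normalize_ddi_label(pair.get("type", "int"))
            gold.add((e1, e2, label))
        record = SentenceRecord(id=sid, text=text, mentions=mentions, gold_relations=gold)
        record.validate()
        records.append(record)
    return records


def write_ddi_xml(records: Sequence[SentenceRecord], path: str | Path) -> None:
    """Serialize records in the DDI XML dialect (inclusive end offsets)."""
    root = etree.Element("document")
    for rec in records:
        sent = etree.SubElement(root, "sentence", id=rec.id, text=rec.text)
        for m in rec.mentions:
            etree.SubElement(
                sent,
                "entity",
                id=m.id,
                type="drug" if m.entity_class == EntityClass.DRUG else m.entity_class.value.lower(),
                charOffset=f"{m.char_start}-{m.char_end - 1}",
                text=m.surface_text,
            )
        gold = _gold_lookup(rec)
        for i, (m1, m2) in enumerate(combinations(rec.mentions, 2)):
            label = gold.get(frozenset((m1.id, m2.id)))
            attrs = {
                "id": f"{rec.id}.p{i}",
                "e1": m1.id,
                "e2": m2.id,
                "ddi": "true" if label else "false",
            }
            if label:
                attrs["type"] = label.removeprefix(_DDI_LABEL_PREFIX)
            etree.SubElement(sent, "pair", **attrs)
    Path(path).write_bytes(
        etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")
    )


# ---------------------------------------------------------------------------
# ChemProt-style TSV triplets
# ---------------------------------------------------------------------------

_ABBREVIATIONS = (
    "e.g",
    "i.e",
    "et al",
    "vs",
    "fig",
    "Fig",
    "approx",
    "ca",
    "resp",
)

_BOUNDARY = re.compile(r"[.?!]+(?=\s+[A-Z0-9])")


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Deterministic rule-based sentence spans over `text`.

    A boundary is a run of ``.?!`` followed by whitespace and an uppercase
    letter or digit, unless the preceding token is a known abbreviation.
    Returns half-open (start, end) spans covering the trimmed sentences.
    """
    spans: list[tuple[int, int]] = []
    start = 0
    for match in _BOUNDARY.finditer(text):
        end = match.end()
        before = text[start : match.start()]
        if any(before.rstrip().endswith(abbr) for abbr in _ABBREVIATIONS):
            continue
        spans.append((start, end))
        start = end
        while start < len(text) and text[start].isspace():
            start += 1
    if start < len(text):
        spans.append((start, len(text)))
    return [(s, e) for s, e in spans if text[s:e].strip()]


_CHEMPROT_TYPES = {
    "CHEMICAL": EntityClass.CHEMICAL,
    "GENE": EntityClass.GENE_PROTEIN,
    "GENE-Y": EntityClass.GENE_PROTEIN,
    "GENE-N": EntityClass.GENE_PROTEIN,
    "PROTEIN": EntityClass.GENE_PROTEIN,
}


def _read_tsv(path: str | Path, n_cols: int) -> list[list[str]]:
    rows = []
    for ln, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) < n_cols:
            raise CorpusParseError(
                f"{Path(path).name}:{ln}: expected {n_cols} tab-separated fields, "
                f"got {len(cols)}"
            )
        rows.append(cols)
    return rows


def read_chemprot_tsv(
    abstracts: str | Path,
    entities: str | Path,
    relations: str | Path,
) -> list[SentenceRecord]:
    """Read ChemProt-style TSV triplets into sentence records.

    File shapes (UTF-8, tab-separated, keyed by document id):

    * abstracts: ``doc_id  title  abstract`` -- document text is the title
      and abstract joined by a single space, offsets relative to that;
    * entities: ``doc_id  entity_id  type  start  end  text`` with type in
      CHEMICAL / GENE / GENE-Y / GENE-N / PROTEIN;
    * relations: ``doc_id  cpr_group  eval_flag  fine_type  Arg1:eid  Arg2:eid``.

    Abstracts are split into sentences by the deterministic rule-based
    splitter; entities spanning a sentence boundary are dropped with a
    warning, and relations whose arguments lie in different sentences are
    dropped with a logged count.
    """
    docs = {
        row[0]: f"{row[1]} {row[2]}" for row in _read_tsv(abstracts, 3)
    }
    mentions_by_doc: dict[str, list[tuple[str, EntityClass, int, int, str]]] = {}
    for row in _read_tsv(entities, 6):
        doc_id, ent_id, etype, start_s, end_s, surface = row[:6]
        if doc_id not in docs:
            raise CorpusValidationError(f"entity {ent_id}: unknown document {doc_id}")
        if etype.upper() not in _CHEMPROT_TYPES:
            raise CorpusValidationError(
                f"entity {ent_id}: unknown entity type {etype!r}"
            )
        mentions_by_doc.setdefault(doc_id, []).append(
            (ent_id, _CHEMPROT_TYPES[etype.upper()], int(start_s), int(end_s), surface)
        )

    def arg_id(raw: str) -> str:
        return raw.split(":", 1)[1] if ":" in raw else raw

    relations_by_doc: dict[str, list[tuple[str, str, str]]] = {}
    for row in _read_tsv(relations, 6):
        doc_id, _group, _flag, fine, a1, a2 = row[:6]
        relations_by_doc.setdefault(doc_id, []).append((arg_id(a1), arg_id(a2), fine))

    records: list[SentenceRecord] = []
    dropped_cross_sentence = 0
    for doc_id, text in docs.items():
        spans = split_sentences(text)
        sentence_of: dict[str, int] = {}
        per_sentence: dict[int, list[EntityMention]] = {i: [] for i in range(len(spans))}
        for ent_id, eclass, start, end, surface in mentions_by_doc.get(doc_id, []):
            hit = next(
                (i for i, (s, e) in enumerate(spans) if s <= start and end <= e), None
            )
            if hit is None:
                logger.warning(
                    "document %s: entity %s spans a sentence boundary; dropped",
                    doc_id,
                    ent_id,
                )
                continue
            s0 = spans[hit][0]
            per_sentence[hit].append(
                EntityMention(ent_id, eclass, start - s0, end - s0, surface)
            )
            sentence_of[ent_id] = hit
        gold_per_sentence: dict[int, set[tuple[str, str, str]]] = {
            i: set() for i in range(len(spans))
        }
        known = set(sentence_of)
        for e1, e2, fine in relations_by_doc.get(doc_id, []):
            for eid in (e1, e2):
                if eid not in {m[0] for m in mentions_by_doc.get(doc_id, [])}:
                    raise CorpusValidationError(
                        f"document {doc_id}: relation {fine} references unknown "
                        f"entity {eid}"
                    )
            if e1 not in known or e2 not in known or sentence_of[e1] != sentence_of[e2]:
                dropped_cross_sentence += 1
                continue
            gold_per_sentence[sentence_of[e1]].add((e1, e2, fine))
        for i, (s, e) in enumerate(spans):
            mentions = resolve_overlaps(per_sentence[i])
            kept = {m.id for m in mentions}
            record = SentenceRecord(
                id=f"{doc_id}.s{i}",
                text=text[s:e],
                mentions=mentions,
                gold_relations={
                    rel for rel in gold_per_sentence[i] if rel[0] in kept and rel[1] in kept
                },
            )
            record.validate()
            records.append(record)
    if dropped_cross_sentence:
        logger.info("dropped %d cross-sentence relations", dropped_cross_sentence)
    return records


# ---------------------------------------------------------------------------
# JSONL instance files
# ---------------------------------------------------------------------------


def write_instances(instances: Iterable[RelationInstance], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for inst in instances:
            fh.write(
                json.dumps(
                    {
                        "sentence_id": inst.sentence_id,
                        "pair": list(inst.pair),
                        "marked_text": inst.marked_text,
                        "label": inst.label,
                        "scheme": inst.scheme.value,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_instances(path: str | Path) -> list[RelationInstance]:
    instances = []
    for ln, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
            instances.append(
                RelationInstance(
                    sentence_id=obj["sentence_id"],
                    pair=tuple(obj["pair"]),
                    marked_text=obj["marked_text"],
                    label=obj["label"],
                    scheme=SchemeName(obj["scheme"]),
                )
            )
        except (json.JSONDecodeError, KeyError, ValueError) as exc:
            raise CorpusParseError(f"{Path(path).name}:{ln}: malformed JSONL line: {exc}") from exc
    return instances
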