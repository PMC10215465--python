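"""Corpus model: readers, label schemes, instance generation, round trips."""

import json

import pytest

from relex.corpus import (
    CPR_EVAL_GROUPS,
    CPR_FINE_LABELS,
    DDI_NEGATIVE_LABEL,
    CorpusParseError,
    EntityClass,
    EntityMention,
    SchemeName,
    SentenceRecord,
    SchemeMismatchError,
    generate_instances,
    get_scheme,
    map_cpr_group,
    mask_record,
    read_chemprot_tsv,
    read_ddi_xml,
    read_instances,
    split_sentences,
    write_instances,
)


def make_ddi_record(n_drugs, gold=(), sid="s0"):
    words = [f"drug{i}" for i in range(n_drugs)]
    text = "interaction of " + " and ".join(words)
    mentions = []
    pos = len("interaction of ")
    for i, w in enumerate(words):
        mentions.append(
            EntityMention(f"{sid}.e{i}", EntityClass.DRUG, pos, pos + len(w), w)
        )
        pos += len(w) + len(" and ")
    return SentenceRecord(
        id=sid,
        text=text,
        mentions=mentions,
        gold_relations={(f"{sid}.e{a}", f"{sid}.e{b}", lab) for a, b, lab in gold},
    )


class TestDdiXml:
    def test_counts_from_fixture(self, ddi_xml_file):
        records = read_ddi_xml(ddi_xml_file)
        assert len(records) == 1
        rec = records[0]
        assert len(rec.mentions) == 3
        assert len(rec.gold_relations) == 2

    def test_mechanism_pairs(self, ddi_xml_file):
        """A sentence with two annotated pharmacokinetic pairs yields two
        gold DDI-mechanism relations."""
        rec = read_ddi_xml(ddi_xml_file)[0]
        labels = [label for _, _, label in rec.gold_relations]
        assert labels == ["DDI-mechanism", "DDI-mechanism"]

    def test_empty_document(self, tmp_path):
        p = tmp_path / "empty.xml"
        p.write_text("<document id='d'/>", encoding="utf-8")
        assert read_ddi_xml(p) == []

    def test_malformed_xml(self, tmp_path):
        p = tmp_path / "bad.xml"
        p.write_text("<document><sentence>", encoding="utf-8")
        with pytest.raises(CorpusParseError):
            read_ddi_xml(p)

    def test_offset_mismatch_is_rejected(self, tmp_path):
        p = tmp_path / "bad_offsets.xml"
        p.write_text(
            '<document><sentence id="s" text="short">'
            '<entity id="e" type="drug" charOffset="0-20" text="too long"/>'
            "</sentence></document>",
            encoding="utf-8",
        )
        with pytest.raises(ValueError, match="s"):
            read_ddi_xml(p)


class TestChemprot:
    def test_sentence_assignment(self, chemprot_files):
        records = read_chemprot_tsv(*chemprot_files)
        assert len(records) == 3
        assert len(records[1].mentions) == 3  # two chemicals + one gene

    def test_in_sentence_relation_retained(self, chemprot_files):
        records = read_chemprot_tsv(*chemprot_files)
        labels = sorted(l for r in records for _, _, l in r.gold_relations)
        assert labels == ["INHIBITOR", "INHIBITOR"]

    def test_cross_sentence_relation_dropped(self, chemprot_files):
        records = read_chemprot_tsv(*chemprot_files)
        assert not any(
            l == "ACTIVATOR" for r in records for _, _, l in r.gold_relations
        )

    def test_offsets_match_surfaces(self, chemprot_files):
        for rec in read_chemprot_tsv(*chemprot_files):
            for m in rec.mentions:
                assert rec.text[m.char_start : m.char_end] == m.surface_text

    def test_abbreviations_do_not_split(self):
        spans = split_sentences("Aspirin, e.g. Bayer, works. It is old.")
        assert len(spans) == 2


class TestCprMapping:
    @pytest.mark.parametrize(
        "fine,group",
        [
            ("ACTIVATOR", "CPR:3"),
            ("ANTAGONIST", "CPR:6"),
            ("SUBSTRATE_PRODUCT-OF", "CPR:9"),
            ("INHIBITOR", "CPR:4"),
            ("AGONIST-INHIBITOR", "CPR:5"),
        ],
    )
    def test_group_of(self, fine, group):
        assert map_cpr_group(fine) == group

    def test_unknown_type(self):
        with pytest.raises(LookupError, match="ACTIVATOR"):
            map_cpr_group("FRIEND")

    def test_fine_labels_surject_onto_eval_groups(self):
        assert len(CPR_FINE_LABELS) == 13
        assert {map_cpr_group(f) for f in CPR_FINE_LABELS} == set(CPR_EVAL_GROUPS)


class TestInstanceGeneration:
    def test_three_drugs_two_mechanisms(self):
        rec = make_ddi_record(
            3, gold=[(0, 1, "DDI-mechanism"), (0, 2, "DDI-mechanism")]
        )
        inst = generate_instances(rec, get_scheme(SchemeName.DDI5))
        assert sorted(i.label for i in inst) == [
            "DDI-false",
            "DDI-mechanism",
            "DDI-mechanism",
        ]
        assert len(inst) == 3

    def test_single_drug_yields_nothing(self):
        rec = make_ddi_record(1)
        assert generate_instances(rec, get_scheme(SchemeName.DDI5)) == []

    def test_all_false_pair_enumeration(self):
        rec = make_ddi_record(5)
        inst = generate_instances(rec, get_scheme(SchemeName.DDI5))
        assert len(inst) == 10  # C(5, 2)
        assert all(i.label == DDI_NEGATIVE_LABEL for i in inst)

    def test_ddi4_drops_false(self):
        rec = make_ddi_record(3, gold=[(0, 1, "DDI-effect")])
        inst = generate_instances(rec, get_scheme(SchemeName.DDI4))
        assert [i.label for i in inst] == ["DDI-effect"]

    @pytest.mark.parametrize("n_drugs", [2, 3, 4, 6])
    def test_ddi5_count_is_m_choose_2(self, n_drugs):
        rec = make_ddi_record(n_drugs)
        assert len(generate_instances(rec, get_scheme(SchemeName.DDI5))) == (
            n_drugs * (n_drugs - 1) // 2
        )

    def test_marked_text_has_exactly_two_marked_spans(self):
        rec = make_ddi_record(4, gold=[(1, 2, "DDI-int")])
        for inst in generate_instances(rec, get_scheme(SchemeName.DDI5)):
            assert inst.marked_text.count("**") == 4  # two spans, two ** each

    def test_masking_replaces_every_mention(self):
        rec = make_ddi_record(3)
        inst = generate_instances(rec, get_scheme(SchemeName.DDI5), mask_entities=True)
        for i in inst:
            assert i.marked_text.count("@DRUG$") == 3
            assert "drug0" not in i.marked_text

    def test_scheme_mismatch(self, chemprot_files):
        records = read_chemprot_tsv(*chemprot_files)
        with pytest.raises(SchemeMismatchError):
            generate_instances(records[1], get_scheme(SchemeName.DDI5))

    def test_cpr_group_vs_fine_labels(self, chemprot_files):
        rec = read_chemprot_tsv(*chemprot_files)[1]
        fine = generate_instances(rec, get_scheme(SchemeName.CPR_FINE))
        group = generate_instances(rec, get_scheme(SchemeName.CPR_GROUP))
        assert sorted(i.label for i in fine) == ["INHIBITOR", "INHIBITOR"]
        assert sorted(i.label for i in group) == ["CPR:4", "CPR:4"]

    def test_chemprot_separators_by_entity_class(self, chemprot_files):
        rec = read_chemprot_tsv(*chemprot_files)[1]
        inst = generate_instances(rec, get_scheme(SchemeName.CPR_FINE))[0]
        assert inst.marked_text.count("##") == 2  # chemical span
        assert inst.marked_text.count("**") == 2  # gene/protein span


class TestMasking:
    def test_mask_is_idempotent(self):
        rec = make_ddi_record(3, gold=[(0, 2, "DDI-advise")])
        once = mask_record(rec)
        twice = mask_record(once)
        assert once == twice

    def test_masked_record_valid(self):
        masked = mask_record(make_ddi_record(4))
        masked.validate()
        assert all(m.surface_text == "@DRUG$" for m in masked.mentions)


class TestJsonlRoundTrip:
    def test_empty(self, tmp_path):
        p = tmp_path / "x.jsonl"
        write_instances([], p)
        assert read_instances(p) == []

    def test_three_instances_three_lines(self, tmp_path):
        rec = make_ddi_record(3)
        inst = generate_instances(rec, get_scheme(SchemeName.DDI5))
        p = tmp_path / "x.jsonl"
        write_instances(inst, p)
        assert len(p.read_text().splitlines()) == 3
        assert read_instances(p) == inst

    def test_random_round_trip(self, tmp_path, rng):
        instances = []
        for _ in range(30):
            n = int(rng.integers(2, 6))
            rec = make_ddi_record(n, sid=f"s{rng.integers(1000)}")
            instances.extend(generate_instances(rec, get_scheme(SchemeName.DDI5)))
        p = tmp_path / "r.jsonl"
        write_instances(instances, p)
        assert read_instances(p) == instances

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "bad.jsonl"
        p.write_text('{"sentence_id": "s"}\nnot json\n', encoding="utf-8")
        with pytest.raises(CorpusParseError, match=":1:"):
            read_instances(p)


def test_read_write_preserves_offsets(ddi_xml_file, tmp_path):
    from relex.corpus import write_ddi_xml

    records = read_ddi_xml(ddi_xml_file)
    out = tmp_path / "rt.xml"
    write_ddi_xml(records, out)
    again = read_ddi_xml(out)
    assert [
        (m.id, m.char_start, m.char_end) for r in again for m in r.mentions
    ] == [(m.id, m.char_start, m.char_end) for r in records for m in r.mentions]
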