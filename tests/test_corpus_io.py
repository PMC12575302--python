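"""Corpus I/O: BRAT parsing, BIO conversion, normalisation, splitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emrkg import corpus_io as cio
from emrkg.corpus_io import (
    AnnotatedDocument,
    AnnParseError,
    BioValidityError,
    ConfigurationError,
    EntitySpan,
    OverlapError,
    TagSequence,
    bio_to_spans,
    is_bio_valid,
    normalize_text,
    parse_ann,
    spans_to_bio,
    split_dataset,
    write_ann,
)


class TestNormalizeText:
    def test_date_and_whitespace_rules(self):
        assert normalize_text("2015年 3月  5日") == "2015-03-05"

    @pytest.mark.parametrize("text", ["", "plain text 123"])
    def test_empty_rule_list_is_identity(self, text):
        assert normalize_text(text, rules=[]) == text

    def test_idempotent(self):
        once = normalize_text("检查 2015年 3月  5日  复查")
        assert normalize_text(once) == once

    def test_malformed_pattern_raises(self):
        with pytest.raises(ConfigurationError):
            normalize_text("x", rules=[("([unclosed", "y")])

    def test_deidentifier_is_stable_per_identifier(self):
        deid = cio.make_deidentifier([r"\b\d{8}\b"], seed=1)
        out1 = deid("id 12345678 and again 12345678")
        a, b = out1.split(" and again ")
        assert a.split()[-1] == b
        assert "12345678" not in out1


class TestParseAnn:
    def test_offsets_and_type_recovered(self):
        text = "x" * 280 + "dull pain in the right shoulder and back for 2 weeks"
        line = f"T1\tdiseases 280 291\t{text[280:291]}"
        doc = parse_ann(text, [line])
        (span,) = doc.spans
        assert (span.span_id, span.entity_type, span.start, span.end) == (
            "T1", "diseases", 280, 291,
        )
        assert span.surface == text[280:291]

    def test_empty_ann_lines(self):
        assert parse_ann("some text", []).spans == []

    def test_offset_outside_text_names_span(self):
        with pytest.raises(AnnParseError, match="T7"):
            parse_ann("short", ["T7\tdiseases 2 99\tx"])

    def test_surface_mismatch_strict_vs_lenient(self):
        text = "abcdef"
        bad = "T1\tdiseases 0 3\tZZZ"
        with pytest.raises(AnnParseError, match="surface"):
            parse_ann(text, [bad], strict=True)
        doc = parse_ann(text, [bad], strict=False)
        assert doc.spans[0].surface == "abc"

    def test_unregistered_type_rejected(self):
        with pytest.raises(AnnParseError, match="unregistered"):
            parse_ann("abcdef", ["T1\tnot_a_type 0 3\tabc"])

    def test_overlap_rejected_listing_both_spans(self):
        lines = ["T1\tdiseases 0 4\tabcd", "T2\tsymptom 2 6\tcdef"]
        with pytest.raises(OverlapError, match="T1.*T2"):
            parse_ann("abcdefgh", lines)

    def test_overlap_keep_longest_repair(self):
        lines = ["T1\tdiseases 0 4\tabcd", "T2\tsymptom 2 6\tcdef"]
        doc = parse_ann("abcdefgh", lines, repair_overlaps=True)
        assert [s.span_id for s in doc.spans] == ["T1"]

    def test_relation_lines_ignored(self):
        doc = parse_ann("abcdef", ["T1\tdiseases 0 3\tabc", "R1\trel Arg1:T1 Arg2:T1"])
        assert len(doc.spans) == 1

    def test_write_parse_roundtrip(self, corpus):
        for doc in corpus:
            lines = write_ann(doc)
            again = parse_ann(doc.text, lines, doc_id=doc.doc_id)
            assert write_ann(again) == lines
            assert again.spans == doc.spans


class TestBioConversion:
    def test_no_spans_all_outside(self):
        doc = AnnotatedDocument("d", "abcdef")
        (seq,) = spans_to_bio(doc)
        assert seq.labels == ["O"] * 6

    def test_interior_span_char_tokens(self):
        doc = AnnotatedDocument(
            "d", "abcdef", [EntitySpan("T1", "diseases", 2, 5, "cde")]
        )
        (seq,) = spans_to_bio(doc)
        assert seq.labels == ["O", "O", "B-diseases", "I-diseases", "I-diseases", "O"]

    def test_adjacent_same_type_spans_restart_b(self):
        doc = AnnotatedDocument(
            "d",
            "abcd",
            [
                EntitySpan("T1", "symptom", 0, 2, "ab"),
                EntitySpan("T2", "symptom", 2, 4, "cd"),
            ],
        )
        (seq,) = spans_to_bio(doc)
        assert seq.labels == ["B-symptom", "I-symptom", "B-symptom", "I-symptom"]

    def test_span_crossing_sentence_boundary_is_error(self):
        doc = AnnotatedDocument(
            "d", "ab。cd", [EntitySpan("T1", "diseases", 1, 4, "b。c")]
        )
        with pytest.raises(ValueError, match="T1"):
            spans_to_bio(doc)

    def test_all_o_yields_no_spans(self):
        seq = TagSequence(list("abc"), ["O", "O", "O"], [(0, 1), (1, 2), (2, 3)])
        assert bio_to_spans(seq) == []

    def test_single_span_recovered(self):
        seq = TagSequence(
            list("abcd"),
            ["O", "B-diseases", "I-diseases", "O"],
            [(0, 1), (1, 2), (2, 3), (3, 4)],
        )
        (span,) = bio_to_spans(seq)
        assert (span.entity_type, span.start, span.end, span.surface) == (
            "diseases", 1, 3, "bc",
        )

    def test_invalid_transition_strict_raises_with_position(self):
        seq = TagSequence(list("abc"), ["O", "I-diseases", "O"])
        with pytest.raises(BioValidityError, match="position 1"):
            bio_to_spans(seq, strict=True)
        # lenient mode opens a new span instead
        (span,) = bio_to_spans(seq, strict=False)
        assert span.entity_type == "diseases"

    def test_roundtrip_on_synthetic_corpus(self, corpus):
        for doc in corpus:
            recovered = [
                (s.entity_type, s.start, s.end, s.surface)
                for seq in spans_to_bio(doc)
                for s in bio_to_spans(seq)
            ]
            gold = [(s.entity_type, s.start, s.end, s.surface) for s in doc.spans]
            assert recovered == gold

    def test_b_count_equals_span_count(self, corpus):
        for doc in corpus:
            n_b = sum(
                lab.startswith("B-")
                for seq in spans_to_bio(doc)
                for lab in seq.labels
            )
            assert n_b == len(doc.spans)

    def test_emitted_sequences_are_bio_valid(self, corpus):
        for doc in corpus:
            for seq in spans_to_bio(doc):
                assert is_bio_valid(seq.labels)

    def test_bio_tsv_roundtrip(self, tag_sequences, tmp_path):
        path = tmp_path / "corpus.bio"
        cio.write_bio(tag_sequences, path)
        back = cio.read_bio(path)
        assert [(s.tokens, s.labels) for s in back] == [
            (s.tokens, s.labels) for s in tag_sequences
        ]

    def test_brat_directory_roundtrip(self, corpus, tmp_path):
        cio.write_brat(corpus, tmp_path / "brat")
        back = cio.read_brat(tmp_path / "brat")
        assert [(d.doc_id, d.text, d.spans) for d in back] == [
            (d.doc_id, d.text, d.spans) for d in corpus
        ]


@st.composite
def _bio_labels(draw):
    """Random BIO-valid label sequences over two entity types."""
    n = draw(st.integers(1, 12))
    labels, prev = [], "O"
    for _ in range(n):
        options = ["O", "B-diseases", "B-symptom"]
        if prev.startswith(("B-", "I-")):
            options.append("I-" + prev[2:])
        lab = draw(st.sampled_from(options))
        labels.append(lab)
        prev = lab
    return labels


@settings(max_examples=50, deadline=None)
@given(_bio_labels())
def test_bio_spans_roundtrip_property(labels):
    seq = TagSequence(
        ["x"] * len(labels), labels, [(i, i + 1) for i in range(len(labels))]
    )
    spans = bio_to_spans(seq)
    doc = AnnotatedDocument("d", "x" * len(labels), spans)
    (back,) = spans_to_bio(doc, split_sentences=False)
    assert back.labels == labels


class TestSplitDataset:
    def test_ten_docs_eight_one_one(self):
        docs = list(range(10))
        train, dev, test = split_dataset(docs, (0.8, 0.1, 0.1), seed=3)
        assert (len(train), len(dev), len(test)) == (8, 1, 1)

    def test_single_doc_all_train(self):
        train, dev, test = split_dataset([1], (1.0, 0.0, 0.0), seed=0)
        assert (train, dev, test) == ([1], [], [])

    def test_partition_exact_and_seeded(self):
        docs = list(range(37))
        a = split_dataset(docs, seed=5)
        b = split_dataset(docs, seed=5)
        c = split_dataset(docs, seed=6)
        assert a == b
        assert sorted(a[0] + a[1] + a[2]) == docs
        assert set(a[0]) & set(a[1]) == set()
        assert set(a[0]) & set(a[2]) == set()
        assert [len(x) for x in c] == [len(x) for x in a]
        assert c != a

    def test_bad_ratios_and_too_few_docs(self):
        with pytest.raises(ValueError):
            split_dataset([1, 2], (0.5, 0.4, 0.0), seed=0)
        with pytest.raises(ValueError):
            split_dataset([1, 2], (0.8, 0.1, 0.1), seed=0)

    def test_nonzero_partitions_get_a_doc(self):
        train, dev, test = split_dataset(list(range(3)), (0.8, 0.1, 0.1), seed=0)
        assert min(len(train), len(dev), len(test)) >= 1
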