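"""Schema, segmentation, BIO conversion and corpus file round-trips."""

import pytest
from hypothesis import given, settings, strategies as st

from picomine import (
    CorpusError,
    Document,
    EntitySpan,
    LabeledSegment,
    GeneratorConfig,
    default_registry,
    generate_corpus,
    read_bio_corpus,
    registry_preset,
    segment_document,
    segment_with_spans,
    spans_to_tags,
    tags_to_spans,
    validate_tags,
    write_bio_corpus,
)


class TestRegistry:
    def test_default_preset_has_ten_elements_with_level_census(self, registry):
        assert len(registry) == 10
        levels = [e.level for e in registry]
        assert (levels.count("A"), levels.count("B"),
                levels.count("C"), levels.count("D")) == (1, 4, 2, 3)
        assert {e.id for e in registry} == {
            "pop_number", "pop_age", "pop_source", "pop_diagnosis", "therapy",
            "out_adverse", "out_shedding", "des_missing", "des_blind",
            "des_random"}

    @pytest.mark.parametrize("preset,n_elements,n_tags",
                             [("default", 10, 21), ("extended", 15, 31)])
    def test_tag_inventory_size(self, preset, n_elements, n_tags):
        reg = registry_preset(preset)
        assert len(reg) == n_elements
        # |tags| = 2*|elements| + 1
        assert len(reg.tag_schema()) == 2 * n_elements + 1 == n_tags

    def test_extended_preset_splits_arm_reported_elements(self, ext_registry):
        ids = {e.id for e in ext_registry}
        assert {"pop_number_t", "pop_number_c", "therapy_t", "therapy_c"} <= ids
        assert "pop_number" not in ids

    def test_unknown_preset_rejected(self):
        with pytest.raises(CorpusError, match="preset"):
            registry_preset("nonexistent")

    def test_duplicate_element_ids_rejected(self):
        from picomine import ElementRegistry, EvidenceElement
        dup = [EvidenceElement("x", "Population", "A"),
               EvidenceElement("x", "Outcome", "B")]
        with pytest.raises(CorpusError, match="unique"):
            ElementRegistry(dup)


class TestSegmentation:
    def test_hard_cut_lengths_without_punctuation(self):
        pieces = segment_document("x" * 300, max_len=128)
        assert [len(p) for p in pieces] == [128, 128, 44]

    def test_cut_prefers_last_sentence_punctuation(self):
        text = "x" * 100 + "。" + "y" * 60
        assert segment_document(text, max_len=128) == ["x" * 100 + "。", "y" * 60]

    def test_empty_text_gives_no_segments(self):
        assert segment_document("") == []

    @given(st.text(alphabet=st.characters(), max_size=600),
           st.integers(min_value=2, max_value=64))
    @settings(max_examples=200, deadline=None)
    def test_segmentation_is_a_partition(self, text, max_len):
        pieces = segment_document(text, max_len)
        assert "".join(pieces) == text
        assert all(1 <= len(p) <= max_len for p in pieces)

    def test_gold_span_never_straddles_a_cut(self):
        # punctuation-free text forces a hard cut at 10, inside the span
        text = "a" * 30
        span = EntitySpan("pop_number", 8, 14, text[8:14])
        pieces = segment_with_spans(text, [span], max_len=10)
        assert "".join(pieces) == text
        bounds, pos = [], 0
        for p in pieces:
            pos += len(p)
            bounds.append(pos)
        assert not any(span.start < b < span.end for b in bounds)


class TestBioConversion:
    def test_span_renders_b_then_i(self, schema):
        tags = spans_to_tags([EntitySpan("pop_number", 0, 2)], 4, schema)
        assert tags == ["B-pop_number", "I-pop_number", "O", "O"]

    def test_no_spans_all_outside(self, schema):
        assert spans_to_tags([], 3, schema) == ["O", "O", "O"]

    def test_overlap_reported_with_both_spans(self, schema):
        spans = [EntitySpan("pop_number", 0, 2), EntitySpan("pop_number", 1, 3)]
        with pytest.raises(CorpusError, match=r"\(0,2,pop_number\).*\(1,3,pop_number\)"):
            spans_to_tags(spans, 4, schema)

    def test_tags_decode_to_spans(self, schema):
        tags = ["B-pop_age", "I-pop_age", "O", "B-therapy"]
        spans = tags_to_spans(tags, schema)
        assert [(s.element, s.start, s.end) for s in spans] == [
            ("pop_age", 0, 2), ("therapy", 3, 4)]

    def test_dangling_i_repaired_as_b(self, schema):
        spans = tags_to_spans(["O", "I-pop_age", "I-pop_age"], schema)
        assert [(s.element, s.start, s.end) for s in spans] == [("pop_age", 1, 3)]

    def test_all_outside_decodes_empty(self, schema):
        assert tags_to_spans(["O", "O"], schema) == []

    def test_unknown_tag_rejected(self, schema):
        with pytest.raises(CorpusError, match="B-unknown"):
            tags_to_spans(["B-unknown"], schema)

    @given(st.data())
    @settings(max_examples=200, deadline=None)
    def test_tags_to_spans_inverts_spans_to_tags(self, schema, data):
        length = data.draw(st.integers(min_value=1, max_value=60))
        elements = [e.id for e in default_registry()]
        spans, cursor = [], 0
        while cursor < length:
            start = data.draw(st.integers(min_value=cursor, max_value=length))
            if start >= length:
                break
            end = data.draw(st.integers(min_value=start + 1, max_value=length))
            if data.draw(st.booleans()):
                spans.append(EntitySpan(data.draw(st.sampled_from(elements)),
                                        start, end))
            cursor = end
        tags = spans_to_tags(spans, length, schema)
        decoded = tags_to_spans(tags, schema)
        assert [(s.element, s.start, s.end) for s in decoded] == \
            [(s.element, s.start, s.end) for s in spans]

    @pytest.mark.parametrize("tags,violations", [
        (["B-pop_age", "I-pop_age"], []),
        (["O", "I-pop_age"], [1]),
        (["B-pop_age", "I-therapy"], [1]),
        (["I-pop_age"], [0]),
    ])
    def test_validate_tags_flags_illegal_transitions(self, schema, tags, violations):
        assert validate_tags(tags, schema) == violations


class TestCorpusFiles:
    def _two_doc_fixture(self, schema):
        s1 = LabeledSegment("0001_2001_A_t", "入30例。",
                            ["O", "B-pop_number", "I-pop_number", "O", "O"])
        s2 = LabeledSegment("0001_2001_A_t", "脱落2例", ["O", "O", "B-out_shedding", "O"])
        s3 = LabeledSegment("0002_2002_B_u", "双盲", ["B-des_blind", "I-des_blind"])
        return [Document("0001_2001_A_t", s1.chars + s2.chars, [s1, s2]),
                Document("0002_2002_B_u", s3.chars, [s3])]

    def test_read_recovers_documents_and_segments(self, tmp_path, schema):
        path = tmp_path / "corpus.bio"
        write_bio_corpus(self._two_doc_fixture(schema), path)
        docs = read_bio_corpus(path, schema)
        assert [d.doc_id for d in docs] == ["0001_2001_A_t", "0002_2002_B_u"]
        assert [len(d.segments) for d in docs] == [2, 1]
        assert docs[0].segments[1].tags == ["O", "O", "B-out_shedding", "O"]

    def test_round_trip_is_byte_identical(self, tmp_path, schema):
        docs, _ = generate_corpus(GeneratorConfig(n_docs=8, seed=3))
        p1, p2 = tmp_path / "a.bio", tmp_path / "b.bio"
        write_bio_corpus(docs, p1)
        write_bio_corpus(read_bio_corpus(p1, schema), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_unknown_tag_error_names_the_tag(self, tmp_path, schema):
        path = tmp_path / "bad.bio"
        path.write_text("###DOC d\n它\tB-unknown\n", encoding="utf-8")
        with pytest.raises(CorpusError, match="B-unknown"):
            read_bio_corpus(path, schema)

    def test_ragged_line_error_carries_line_number(self, tmp_path, schema):
        path = tmp_path / "bad.bio"
        path.write_text("###DOC d\n它\tO\n奇怪行\n", encoding="utf-8")
        with pytest.raises(CorpusError, match="line 3"):
            read_bio_corpus(path, schema)

    def test_document_requires_segments_to_reconstruct_text(self):
        seg = LabeledSegment("d", "ab", ["O", "O"])
        with pytest.raises(CorpusError, match="reconstruct"):
            Document("d", "abc", [seg])
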