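"""Generator determinism, offset integrity, and perturbation semantics."""

import numpy as np
import pytest

from picomine import (
    ElementRegistry,
    EvidenceElement,
    GeneratorConfig,
    MatchConfig,
    builtin_template_bank,
    generate_corpus,
    inject_ocr_noise,
    inject_redundancy,
    match_spans,
    read_bio_corpus,
    rules_only_extract,
    starter_ruleset,
    write_bio_corpus,
)
from picomine.synthetic import GeneratorError


def gold_span_map(docs, schema):
    return {d.doc_id: d.gold_spans(schema) for d in docs}


class TestGeneration:
    def test_same_seed_gives_byte_identical_corpora(self, tmp_path, schema):
        paths = []
        for name in ("a.bio", "b.bio"):
            docs, _ = generate_corpus(GeneratorConfig(n_docs=15, seed=42))
            path = tmp_path / name
            write_bio_corpus(docs, path)
            paths.append(path)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_inclusion_probability_one_covers_every_element(self, registry, schema):
        docs, _ = generate_corpus(GeneratorConfig(n_docs=10, seed=1,
                                                  elements_per_doc=1.0))
        for doc in docs:
            present = {s.element for s in doc.gold_spans(schema)}
            assert present == {e.id for e in registry}

    @pytest.mark.parametrize("noise", [0.0, 0.2])
    def test_gold_offsets_address_their_slots(self, schema, noise):
        docs, gold = generate_corpus(GeneratorConfig(n_docs=10, seed=4,
                                                     ocr_noise_rate=noise))
        for doc, record in zip(docs, gold):
            for span in doc.gold_spans(schema):
                assert doc.text[span.start:span.end] == span.text
            for values in record.elements.values():
                for v in values:
                    assert doc.text[v.start:v.end] == v.value

    def test_gold_records_carry_numeric_values_for_counts(self, registry):
        _, gold = generate_corpus(GeneratorConfig(n_docs=10, seed=4,
                                                  elements_per_doc=1.0))
        for record in gold:
            for elem, values in record.elements.items():
                if registry.level_of(elem) == "D":
                    assert all(v.numeric is not None for v in values)

    def test_corpus_round_trips_through_bio_files(self, tmp_path, schema):
        docs, _ = generate_corpus(GeneratorConfig(n_docs=6, seed=8))
        path = tmp_path / "c.bio"
        write_bio_corpus(docs, path)
        loaded = read_bio_corpus(path, schema)
        assert [d.text for d in loaded] == [d.text for d in docs]
        assert [[s.tags for s in d.segments] for d in loaded] == \
            [[s.tags for s in d.segments] for d in docs]

    def test_missing_template_coverage_rejected(self):
        registry = ElementRegistry(
            [EvidenceElement("unheard_of", "Outcome", "D")], name="custom")
        with pytest.raises(GeneratorError, match="unheard_of"):
            generate_corpus(GeneratorConfig(n_docs=1, seed=0), registry)

    def test_doc_ids_follow_number_year_author_title_form(self):
        docs, _ = generate_corpus(GeneratorConfig(n_docs=3, seed=2))
        for doc in docs:
            number, year, author, title = doc.doc_id.split("_")
            assert number.isdigit() and year.isdigit() and author and title

    def test_builtin_bank_covers_both_presets(self, registry, ext_registry):
        for reg in (registry, ext_registry):
            bank = builtin_template_bank(reg)
            bank.check_covers([e.id for e in reg])


class TestRuleTemplateCoDesign:
    def test_rules_only_reaches_full_recall_on_counts_without_noise(self, registry):
        """Number-valued elements: templates and starter rules are
        co-designed, so the rule baseline misses none of them."""
        docs, _ = generate_corpus(GeneratorConfig(n_docs=25, seed=21,
                                                  ocr_noise_rate=0.0))
        rs = starter_ruleset(registry)
        schema = registry.tag_schema()
        missed = 0
        total = 0
        for doc in docs:
            record = rules_only_extract(doc.text, rs, registry, doc_id=doc.doc_id)
            pred = {(s.element, s.start, s.end) for s in record.spans()}
            for span in doc.gold_spans(schema):
                if registry.level_of(span.element) != "D":
                    continue
                total += 1
                if (span.element, span.start, span.end) not in pred:
                    missed += 1
        assert total > 0 and missed == 0


class TestOcrNoise:
    def test_rate_zero_is_identity(self):
        docs, _ = generate_corpus(GeneratorConfig(n_docs=3, seed=6,
                                                  ocr_noise_rate=0.0))
        noised = inject_ocr_noise(docs[0], 0.0, seed=1)
        assert noised.text == docs[0].text

    def test_rate_one_substitutes_every_unprotected_character(self, schema):
        docs, _ = generate_corpus(GeneratorConfig(n_docs=3, seed=6,
                                                  ocr_noise_rate=0.0))
        doc = docs[0]
        protected = np.zeros(len(doc.text), dtype=bool)
        for s in doc.gold_spans(schema):
            protected[s.start:s.end] = True
        noised = inject_ocr_noise(doc, 1.0, seed=1)
        for i, (a, b) in enumerate(zip(doc.text, noised.text)):
            assert (a == b) == bool(protected[i])

    def test_gold_spans_survive_noise(self, schema):
        docs, _ = generate_corpus(GeneratorConfig(n_docs=3, seed=6,
                                                  ocr_noise_rate=0.0))
        noised = inject_ocr_noise(docs[0], 0.7, seed=3)
        assert [s.text for s in noised.gold_spans(schema)] == \
            [s.text for s in docs[0].gold_spans(schema)]

    def test_seeded_noise_is_reproducible(self):
        docs, _ = generate_corpus(GeneratorConfig(n_docs=2, seed=6,
                                                  ocr_noise_rate=0.0))
        assert inject_ocr_noise(docs[0], 0.3, seed=9).text == \
            inject_ocr_noise(docs[0], 0.3, seed=9).text


@pytest.fixture(scope="module")
def corpus(schema):
    docs, _ = generate_corpus(GeneratorConfig(n_docs=10, seed=14,
                                              ocr_noise_rate=0.0))
    return docs, gold_span_map(docs, schema)


class TestRedundancy:
    def test_rate_zero_returns_gold(self, corpus):
        docs, gold = corpus
        pred, stats = inject_redundancy(docs, gold, rate=0.0, k_max=5, seed=1)
        assert stats["n_selected"] == 0
        for doc_id, spans in gold.items():
            assert [(s.start, s.end) for s in pred[doc_id]] == \
                [(s.start, s.end) for s in spans]

    def test_full_redundancy_matches_relaxed_but_not_strict(self, corpus):
        """With every span extended by at most tol_abs characters, relaxed
        matching recovers all gold spans while strict matching only keeps
        the spans the text end prevented from growing."""
        docs, gold = corpus
        k_max = 5  # <= default tol_abs of 10
        pred, stats = inject_redundancy(docs, gold, rate=1.0, k_max=k_max, seed=2)
        strict_tp = relaxed_tp = n_gold = 0
        for doc_id, gold_spans in gold.items():
            strict_tp += match_spans(gold_spans, pred[doc_id],
                                     MatchConfig(mode="strict")).tp
            relaxed_tp += match_spans(gold_spans, pred[doc_id],
                                      MatchConfig(mode="relaxed")).tp
            n_gold += len(gold_spans)
        assert relaxed_tp == n_gold
        assert strict_tp == stats["n_clipped_unchanged"]
        assert stats["n_selected"] == stats["n_spans"] == n_gold

    def test_seeded_perturbation_is_reproducible(self, corpus):
        docs, gold = corpus
        a, _ = inject_redundancy(docs, gold, rate=0.4, k_max=4, seed=7)
        b, _ = inject_redundancy(docs, gold, rate=0.4, k_max=4, seed=7)
        assert {k: [(s.start, s.end) for s in v] for k, v in a.items()} == \
            {k: [(s.start, s.end) for s in v] for k, v in b.items()}
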