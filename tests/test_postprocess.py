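"""Post-processing rules and passage derivation."""

import pytest

from chemtagger.corpus_io import EntityAnnotation, PatentDocument, validate_annotation
from chemtagger.postprocess import (
    StructureWordLexicon,
    derive_cpd,
    is_balanced,
    merge_structure_words,
    postprocess,
    propagate_exact_matches,
    remove_unbalanced,
)


def ann(doc, section, start, end, conf=0.9, etype="TRIVIAL"):
    return EntityAnnotation(
        doc.doc_id, section, start, end, doc.section_text(section)[start:end],
        etype, conf,
    )


class TestPropagation:
    def test_second_occurrence_added(self):
        doc = PatentDocument("D", "t", "aspirin was given; aspirin worked.")
        preds = [ann(doc, "A", 0, 7)]
        out = propagate_exact_matches([doc], preds)
        assert {(p.start, p.end) for p in out} == {(0, 7), (19, 26)}
        added = next(p for p in out if p.start == 19)
        assert added.confidence == 0.9 and added.entity_type == "TRIVIAL"

    def test_in_word_substring_not_added(self):
        doc = PatentDocument("D", "t", "pirin is not aspirin here.")
        preds = [ann(doc, "A", 0, 5)]  # "pirin" as a standalone word
        out = propagate_exact_matches([doc], preds)
        # "pirin" inside "aspirin" must not fire (boundary guard)
        assert {(p.start, p.end) for p in out} == {(0, 5)}

    def test_occurrence_overlapping_existing_prediction_skipped(self):
        doc = PatentDocument("D", "t", "aspirin aspirin")
        preds = [ann(doc, "A", 0, 7), ann(doc, "A", 8, 15)]
        out = propagate_exact_matches([doc], preds)
        assert len(out) == 2

    def test_propagates_into_title(self):
        doc = PatentDocument("D", "aspirin salts", "aspirin was tested.")
        preds = [ann(doc, "A", 0, 7)]
        out = propagate_exact_matches([doc], preds)
        assert any(p.section == "T" and (p.start, p.end) == (0, 7) for p in out)


class TestBracketFilter:
    @pytest.mark.parametrize(
        "surface,kept",
        [
            ("(S-1-P", False),
            ("sphingosine-1-phosphate (S-1-P)", True),
            ("[14C]glucose", True),
            ("a)b(", False),
            ("{only-braces", True),  # braces are ignored by the rule
        ],
    )
    def test_balance_rule(self, surface, kept):
        assert is_balanced(surface) is kept

    def test_remove_unbalanced_filters(self):
        doc = PatentDocument("D", "t", "(S-1-P and sphingosine (SPH) here.")
        preds = [ann(doc, "A", 0, 6), ann(doc, "A", 11, 28)]
        assert preds[0].text == "(S-1-P"
        out = remove_unbalanced(preds)
        assert [p.text for p in out] == ["sphingosine (SPH)"]

    def test_idempotent(self):
        doc = PatentDocument("D", "t", "(S-1-P and water here.")
        preds = [ann(doc, "A", 0, 6), ann(doc, "A", 11, 16)]
        once = remove_unbalanced(preds)
        assert remove_unbalanced(once) == once


class TestStructureWordMerge:
    def test_preceding_word_merged(self):
        doc = PatentDocument("D", "t", "Chiral tricyclic compounds with activity.")
        preds = [ann(doc, "A", 7, 16)]
        assert preds[0].text == "tricyclic"
        lex = StructureWordLexicon({"chiral"})
        (merged,) = merge_structure_words([doc], preds, lex)
        assert (merged.start, merged.end, merged.text) == (0, 16, "Chiral tricyclic")

    def test_following_word_merged(self):
        doc = PatentDocument("D", "t", "a 1,6-naphthyridonecarboxylic acid salt.")
        preds = [ann(doc, "A", 2, 29)]
        lex = StructureWordLexicon({"acid"})
        (merged,) = merge_structure_words([doc], preds, lex)
        assert merged.text == "1,6-naphthyridonecarboxylic acid"

    def test_no_adjacent_lexicon_word_unchanged(self):
        doc = PatentDocument("D", "t", "pure benzene was isolated.")
        preds = [ann(doc, "A", 5, 12)]
        lex = StructureWordLexicon({"acid"})
        assert merge_structure_words([doc], preds, lex) == preds

    def test_hyphen_separator_merges(self):
        doc = PatentDocument("D", "t", "the chiral-benzene mixture.")
        preds = [ann(doc, "A", 11, 18)]
        lex = StructureWordLexicon({"chiral"})
        (merged,) = merge_structure_words([doc], preds, lex)
        assert merged.text == "chiral-benzene"

    def test_fixpoint_within_pass_limit(self):
        doc = PatentDocument("D", "t", "a chiral carboxylic acid here.")
        preds = [ann(doc, "A", 9, 19)]  # "carboxylic"
        lex = StructureWordLexicon({"chiral", "acid"})
        (merged,) = merge_structure_words([doc], preds, lex)
        assert merged.text == "chiral carboxylic acid"
        again = merge_structure_words([doc], [merged], lex)
        assert again == [merged]


class TestPostprocessPipeline:
    def test_rules_compose_and_revalidate(self):
        doc = PatentDocument(
            "D", "t", "Chiral tricyclic compounds and tricyclic again."
        )
        preds = [ann(doc, "A", 7, 16)]
        lex = StructureWordLexicon({"chiral"})
        out = postprocess([doc], preds, lex)
        for p in out:
            validate_annotation(p, doc)
        # propagation found the second "tricyclic"; merge extended the first
        assert {(p.start, p.end) for p in out} == {(0, 16), (31, 40)}

    def test_substring_invariant_never_violated(self, small_corpus):
        docs = small_corpus.documents
        preds = [a for i, a in enumerate(small_corpus.annotations) if i % 2 == 0]
        lex = StructureWordLexicon(small_corpus.structure_lexicon)
        by_id = {d.doc_id: d for d in docs}
        for p in postprocess(docs, preds, lex):
            validate_annotation(p, by_id[p.doc_id])


class TestDeriveCpd:
    def _docs(self):
        return [
            PatentDocument("D1", "title one", "abstract one"),
            PatentDocument("D2", "title two", "abstract two"),
        ]

    def test_title_entity_confidence(self):
        docs = self._docs()
        preds = [EntityAnnotation("D1", "T", 0, 5, "title", confidence=0.8)]
        out = derive_cpd(docs, preds)
        assert out[0].doc_id == "D1" and out[0].section == "T"
        assert out[0].confidence == 0.8

    def test_max_pooling_over_entities(self):
        docs = self._docs()
        preds = [
            EntityAnnotation("D1", "A", 0, 8, "abstract", confidence=0.3),
            EntityAnnotation("D1", "A", 9, 12, "one", confidence=0.9),
        ]
        out = derive_cpd(docs, preds)
        assert out[0].confidence == 0.9

    def test_emits_every_section_with_zero_default(self):
        docs = self._docs()
        out = derive_cpd(docs, [])
        assert len(out) == 4 and all(s.confidence == 0.0 for s in out)

    def test_zero_sections_ranked_last(self):
        docs = self._docs()
        preds = [EntityAnnotation("D2", "A", 0, 8, "abstract", confidence=0.5)]
        out = derive_cpd(docs, preds)
        assert (out[0].doc_id, out[0].section) == ("D2", "A")
        assert all(s.confidence == 0.0 for s in out[1:])

    def test_always_two_per_document(self, small_corpus):
        out = derive_cpd(small_corpus.documents, small_corpus.annotations)
        assert len(out) == 2 * len(small_corpus.documents)
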