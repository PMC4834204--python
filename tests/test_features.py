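"""Feature extraction: orthographic, lexicon-driven and representation features."""

import pytest

from chemtagger.brown import ClusterPaths
from chemtagger.embeddings import BinarizedEmbedding
from chemtagger.features import (
    AffixLexicon,
    FeatureConfig,
    GeneLexicon,
    Resources,
    SemanticLexicon,
    affixes,
    assemble,
    char_ngrams,
    chemical_affixes,
    extract_sentence,
    lexicon_annotate,
    representation_features,
    word_pattern,
)
from chemtagger.preprocess import tokenize

import numpy as np


class TestOrthographic:
    @pytest.mark.parametrize(
        "surface,full,collapsed",
        [
            ("Benzyl", "Aaaaaa", "Aa"),
            ("C6H6", "A0A0", "A0A0"),
            ("1,6-acid", "0,0-aaaa", "0,0-a"),
        ],
    )
    def test_word_pattern(self, surface, full, collapsed):
        assert word_pattern(surface) == (full, collapsed)

    def test_affixes_chemical_name(self):
        prefixes, suffixes = affixes("benzylamino")
        assert prefixes == {"b", "be", "ben"}
        assert suffixes == {"o", "no", "ino"}

    def test_affixes_short_word_skips_long_m(self):
        prefixes, suffixes = affixes("of", (1, 2, 3))
        assert prefixes == {"o", "of"} and suffixes == {"f", "of"}

    def test_affixes_single_character(self):
        assert affixes("A") == ({"A"}, {"A"})

    def test_char_ngrams_chemical_name(self):
        expected = {
            "be", "ben", "en", "enz", "nz", "nzy", "zy", "zyl", "yl", "yla",
            "la", "lam", "am", "ami", "mi", "min", "in", "ino", "no",
        }
        assert char_ngrams("benzylamino") == expected
        assert len(expected) == 19

    def test_char_ngrams_set_semantics(self):
        assert char_ngrams("ab", (2, 3)) == {"ab"}
        assert char_ngrams("aaa", (2,)) == {"aa"}

    def test_affix_ngram_size_bound(self):
        """|affixes| + |ngrams| <= sum_m 2 + sum_n (L - n + 1), tight sans dups."""
        for surface in ["benzylamino", "aaa", "xy", "C6H6O2"]:
            L = len(surface)
            pre, suf = affixes(surface)
            grams = char_ngrams(surface)
            bound = sum(2 for m in (1, 2, 3) if m <= L) + sum(
                max(L - n + 1, 0) for n in (2, 3)
            )
            assert len(pre) + len(suf) + len(grams) <= bound


class TestLexicons:
    def test_chemical_affixes_both_ends(self):
        lex = AffixLexicon({"benzyl", "amino", "hydroxyl", "cyclic"})
        assert chemical_affixes("benzylamino", lex) == {
            "prefix": "benzyl",
            "suffix": "amino",
        }

    def test_chemical_affixes_no_match(self):
        lex = AffixLexicon({"benzyl", "amino"})
        assert chemical_affixes("water", lex) == {}

    def test_chemical_affixes_prefix_only(self):
        lex = AffixLexicon({"benzyl", "amino"})
        assert chemical_affixes("aminobenzene", lex) == {"prefix": "amino"}

    def test_chemical_affixes_longest_wins(self):
        lex = AffixLexicon({"a", "am", "amino"})
        assert chemical_affixes("aminol", lex)["prefix"] == "amino"

    def test_semantic_multiword_longest_match(self):
        toks = tokenize("hepatitis C virus infection")
        lex = SemanticLexicon.from_pairs(
            {"hepatitis C virus": "Virus", "hepatitis": "Disease"}
        )
        assert lexicon_annotate(toks, lex) == ["Virus", "Virus", "Virus", None]

    def test_semantic_longer_beats_shorter_at_same_start(self):
        toks = tokenize("amino acid")
        lex = SemanticLexicon.from_pairs({"amino": "Group", "amino acid": "AA"})
        assert lexicon_annotate(toks, lex) == ["AA", "AA"]

    def test_no_entries_match(self):
        toks = tokenize("nothing here")
        lex = SemanticLexicon.from_pairs({"water": "Substance"})
        assert lexicon_annotate(toks, lex) == [None, None]

    def test_gene_lexicon_single_token(self):
        toks = tokenize("the BRCA1 gene")
        tags = lexicon_annotate(toks, GeneLexicon({"BRCA1"}))
        assert tags == [None, "GENE", None]


class TestRepresentationFeatures:
    def test_preannotation_label_type(self):
        res = Resources(pre_annotations={0: ("B", "TRIVIAL")})
        feats = representation_features("hydrocodone", res, FeatureConfig(), 0)
        assert feats == {"PRE=B_TRIVIAL"}

    def test_brown_path_and_prefixes(self):
        paths = ClusterPaths({"oxygen": ("110110110110", 7)})
        res = Resources(cluster_paths=paths)
        cfg = FeatureConfig(brown_prefix_lengths=(4, 6))
        feats = representation_features("oxygen", res, cfg, 0)
        assert feats == {"BC=110110110110", "BC4=1101", "BC6=110110"}

    def test_embedding_nonzero_dimensions_only(self):
        emb = BinarizedEmbedding(["acid"], np.array([["+", "0", "-"]]))
        res = Resources(binarized=emb)
        feats = representation_features("acid", res, FeatureConfig(), 0)
        assert feats == {"EMB0=+", "EMB2=-"}

    def test_word_absent_from_all_resources(self):
        res = Resources(
            cluster_paths=ClusterPaths({}),
            binarized=BinarizedEmbedding([], np.zeros((0, 3), dtype="<U1")),
        )
        assert representation_features("novelword", res, FeatureConfig(), 0) == set()


class TestAssemble:
    def test_padding_sentinels_on_single_token(self):
        toks = tokenize("aspirin")
        feats = assemble(toks, 0, config=FeatureConfig(window=2))
        assert "W-1=<s>" in feats and "W1=</s>" in feats

    def test_all_families_off_leaves_word_unigram(self):
        cfg = FeatureConfig(
            use_words=False, use_pos=False, use_pattern=False, use_affixes=False,
            use_ngrams=False, use_chemical_affixes=False, use_gene_lexicon=False,
            use_semantic=False, use_preannotation=False, use_brown=False,
            use_embedding=False,
        )
        toks = tokenize("aspirin works")
        assert assemble(toks, 0, config=cfg) == {"W0=aspirin"}

    def test_index_out_of_range(self):
        with pytest.raises(IndexError):
            assemble(tokenize("one two"), 5)

    def test_frozen_feature_count_regression(self):
        """Exhaustively enumerated once for a fixed 3-token sentence, w=1."""
        toks = tokenize("acid is good")
        cfg = FeatureConfig(window=1)
        feats = assemble(toks, 1, config=cfg)
        # independent enumeration for position 1 of "acid is good", w=1:
        # word unigrams W-1,W0,W1 (3) + lowercased WL duplicates (3)
        # + bigrams WB-1,WB0 (2) + trigram WT-1 (1)
        # + PAT,PATC (2) + prefixes {i,is} (2) + suffixes {s,is} (2)
        # + ngrams of "is" {is} (1); no POS/lexicons/resources
        expected = {
            "W-1=acid", "W0=is", "W1=good",
            "WL-1=acid", "WL0=is", "WL1=good",
            "WB-1=acid|is", "WB0=is|good", "WT-1=acid|is|good",
            "PAT=aa", "PATC=a",
            "PRE1=i", "PRE2=is", "SUF1=s", "SUF2=is", "NG=is",
        }
        assert feats == frozenset(expected)

    def test_deterministic_and_position_local(self, small_corpus):
        """A token's features depend only on its own sentence."""
        from chemtagger.pipeline import iter_sentences

        refs = iter_sentences(small_corpus.documents[:3])
        first = [extract_sentence(r.tokens) for r in refs]
        second = [extract_sentence(r.tokens) for r in reversed(refs)]
        assert first == list(reversed(second))

    def test_disabled_family_yields_subset(self):
        toks = tokenize("1,6-benzylamino acid")
        res = Resources(affix_lexicon=AffixLexicon({"benzyl", "amino", "acid"}))
        full = assemble(toks, 4, res, FeatureConfig())
        reduced = assemble(toks, 4, res, FeatureConfig(use_ngrams=False))
        assert reduced < full
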