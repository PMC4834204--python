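"""Per-token sparse feature extraction.

Each token position yields an unordered set of ``name=value`` strings: the
union of baseline features (context word unigrams/bigrams/trigrams, optional
POS n-grams, orthographic word patterns, character prefixes/suffixes and
n-grams), domain-knowledge features (chemical affix morphemes, a gene/protein
lexicon, semantic-type context tags, external pre-annotations) and
unsupervised word-representation features (Brown cluster bit-string paths and
binarized embedding symbols).

Feature name registry
---------------------
=========  =====================================================
``W<k>``    word unigram at window offset k (``W0`` = the token)
``WL<k>``   lowercased duplicate of ``W<k>``
``WB<k>``   word bigram starting at offset k
``WT<k>``   word trigram starting at offset k
``P<k>``/``PB<k>``/``PT<k>``  POS unigram/bigram/trigram
``PAT``/``PATC``  full / collapsed orthographic pattern of the token
``PRE<m>``/``SUF<m>``  first/last m characters
``NG``      character n-gram (set semantics)
``CHEMPRE``/``CHEMSUF``  longest chemical-morpheme prefix/suffix
``GENE``    token matches the gene/protein lexicon
``SEM<k>``  semantic-type tag at window offset k
``PRE``     external pre-annotation ``<label>_<type>``
``BC``/``BC<k>``  Brown path, full and length-k prefixes
``EMB<j>``  binarized embedding symbol of dimension j (non-zero only)
=========  =====================================================

Sentence edges are padded with the sentinels ``<s>`` and ``</s>``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .brown import ClusterPaths
from .embeddings import BinarizedEmbedding
from .preprocess import Token

PAD_LEFT = "<s>"
PAD_RIGHT = "</s>"


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-family toggles and hyperparameters.

    window is the context radius for word/POS/semantic features (2 keeps the
    model local while still seeing both neighbors of a two-token mention);
    affix_m and ngram_n are the character prefix/suffix and n-gram lengths;
    brown_prefix_lengths are the path-prefix depths emitted besides the full
    path, so coarse and fine cluster granularities are both available.
    """

    window: int = 2
    affix_m: tuple[int, ...] = (1, 2, 3)
    ngram_n: tuple[int, ...] = (2, 3)
    brown_prefix_lengths: tuple[int, ...] = (4, 6, 10)
    use_words: bool = True
    use_pos: bool = True
    use_pattern: bool = True
    use_affixes: bool = True
    use_ngrams: bool = True
    use_chemical_affixes: bool = True
    use_gene_lexicon: bool = True
    use_semantic: bool = True
    use_preannotation: bool = True
    use_brown: bool = True
    use_embedding: bool = True

    def __post_init__(self) -> None:
        if self.window < 0:
            raise ValueError("window must be >= 0")
        if any(m < 1 for m in self.affix_m) or any(n < 1 for n in self.ngram_n):
            raise ValueError("affix/ngram lengths must be >= 1")


class AffixLexicon:
    """Chemical morphemes: functional groups and structure fragments."""

    def __init__(self, morphemes) -> None:
        cleaned = frozenset(m.lower() for m in morphemes)
        if any((not m) or any(ch.isspace() for ch in m) for m in cleaned):
            raise ValueError("morphemes must be non-empty and whitespace-free")
        self.morphemes = cleaned

    def __repr__(self) -> str:
        return f"AffixLexicon({len(self.morphemes)} morphemes)"


class GeneLexicon:
    """Gene/protein surfaces treated as single-token decoy indicators."""

    def __init__(self, surfaces) -> None:
        self.surfaces = frozenset(s.lower() for s in surfaces if s)

    def __contains__(self, token: str) -> bool:
        return token.lower() in self.surfaces

    def __repr__(self) -> str:
        return f"GeneLexicon({len(self.surfaces)} surfaces)"


@dataclass
class SemanticLexicon:
    """Multi-word term -> semantic-type label (UMLS-style, file-driven)."""

    entries: dict[tuple[str, ...], str]

    @classmethod
    def from_pairs(cls, pairs: Mapping[str, str]) -> "SemanticLexicon":
        entries = {
            tuple(term.lower().split()): label for term, label in pairs.items() if term
        }
        return cls(entries)

    @property
    def max_len(self) -> int:
        return max((len(t) for t in self.entries), default=0)


@dataclass
class Resources:
    """Optional external resources; a missing one disables its feature family."""

    affix_lexicon: AffixLexicon | None = None
    gene_lexicon: GeneLexicon | None = None
    semantic_lexicon: SemanticLexicon | None = None
    cluster_paths: ClusterPaths | None = None
    binarized: BinarizedEmbedding | None = None
    pre_annotations: Mapping[int, tuple[str, str]] | None = field(default=None)
    # pre_annotations: token position -> (BIO label, entity type) for one sentence


def read_wordlist(path: str | Path) -> frozenset[str]:
    with open(path, encoding="utf-8") as handle:
        return frozenset(line.strip() for line in handle if line.strip())


def read_semantic_lexicon(path: str | Path) -> SemanticLexicon:
    pairs: dict[str, str] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            term, sep, label = line.partition("\t")
            if not sep or not term or not label:
                raise ValueError(f"{path}:{lineno}: expected 'term<TAB>type'")
            pairs[term] = label
    return SemanticLexicon.from_pairs(pairs)


def word_pattern(surface: str) -> tuple[str, str]:
    """Orthographic shape: uppercase->A, lowercase->a, digit->0, rest kept.

    Returns the full pattern and a collapsed form with repeats squeezed.
    """
    full = "".join(
        "A" if c.isupper() else "a" if c.islower() else "0" if c.isdigit() else c
        for c in surface
    )
    collapsed = []
    for c in full:
        if not collapsed or collapsed[-1] != c:
            collapsed.append(c)
    return full, "".join(collapsed)


def affixes(
    surface: str, m_set: Sequence[int] = (1, 2, 3)
) -> tuple[set[str], set[str]]:
    """First-m and last-m character substrings for each m <= len(surface)."""
    prefixes = {surface[:m] for m in m_set if m <= len(surface)}
    suffixes = {surface[-m:] for m in m_set if m <= len(surface)}
    return prefixes, suffixes


def char_ngrams(surface: str, n_set: Sequence[int] = (2, 3)) -> set[str]:
    """All contiguous character substrings of each length n (types, not positions)."""
    return {
        surface[i : i + n]
        for n in n_set
        for i in range(len(surface) - n + 1)
    }


def chemical_affixes(
    surface: str, lexicon: AffixLexicon
) -> dict[str, str]:
    """Longest lexicon morpheme that prefixes / suffixes the token (case-insensitive)."""
    lowered = surface.lower()
    out: dict[str, str] = {}
    best_pre = best_suf = ""
    for morpheme in lexicon.morphemes:
        if lowered.startswith(morpheme) and len(morpheme) > len(best_pre):
            best_pre = morpheme
        if lowered.endswith(morpheme) and len(morpheme) > len(best_suf):
            best_suf = morpheme
    if best_pre:
        out["prefix"] = best_pre
    if best_suf:
        out["suffix"] = best_suf
    return out


def lexicon_annotate(
    tokens: Sequence[Token], lexicon: SemanticLexicon | GeneLexicon
) -> list[str | None]:
    """Greedy left-to-right longest multi-token match; matched tokens get the label.

    A :class:`GeneLexicon` is treated as single-token terms labelled ``GENE``.
    """
    if isinstance(lexicon, GeneLexicon):
        sem = SemanticLexicon({(s,): "GENE" for s in lexicon.surfaces})
    else:
        sem = lexicon
    tags: list[str | None] = [None] * len(tokens)
    lowered = [t.surface.lower() for t in tokens]
    max_len = sem.max_len
    i = 0
    while i < len(tokens):
        matched = 0
        label = None
        for length in range(min(max_len, len(tokens) - i), 0, -1):
            candidate = tuple(lowered[i : i + length])
            if candidate in sem.entries:
                matched, label = length, sem.entries[candidate]
                break
        if matched:
            for k in range(i, i + matched):
                tags[k] = label
            i += matched
        else:
            i += 1
    return tags


def representation_features(
    surface: str,
    resources: Resources,
    config: FeatureConfig,
    position: int,
) -> set[str]:
    """Pre-annotation, Brown-path and binarized-embedding features of one token.

    Words absent from a resource's vocabulary contribute nothing for that
    family (no sentinel feature).
    """
    feats: set[str] = set()
    if config.use_preannotation and resources.pre_annotations:
        entry = resources.pre_annotations.get(position)
        if entry is not None:
            label, etype = entry
            feats.add(f"PRE={label}_{etype}")
    if config.use_brown and resources.cluster_paths is not None:
        path = resources.cluster_paths.path(surface.lower())
        if path is not None:
            feats.add(f"BC={path}")
            for k in config.brown_prefix_lengths:
                if k <= len(path):
                    feats.add(f"BC{k}={path[:k]}")
    if config.use_embedding and resources.binarized is not None:
        row = resources.binarized.lookup(surface.lower())
        if row is not None:
            for j, sym in enumerate(row):
                if sym != "0":
                    feats.add(f"EMB{j}={sym}")
    return feats


def _window_word(tokens: Sequence[Token], i: int) -> str:
    if i < 0:
        return PAD_LEFT
    if i >= len(tokens):
        return PAD_RIGHT
    return tokens[i].surface


def _window_pos(tokens: Sequence[Token], i: int) -> str:
    if i < 0:
        return PAD_LEFT
    if i >= len(tokens):
        return PAD_RIGHT
    return tokens[i].pos or "NONE"


def assemble(
    tokens: Sequence[Token],
    i: int,
    resources: Resources | None = None,
    config: FeatureConfig | None = None,
) -> frozenset[str]:
    """Full feature set for token *i* of one sentence."""
    if not 0 <= i < len(tokens):
        raise IndexError(f"token index {i} out of range for sentence of {len(tokens)}")
    resources = resources or Resources()
    config = config or FeatureConfig()
    w = config.window
    feats: set[str] = {f"W0={tokens[i].surface}"}

    if config.use_words:
        for k in range(-w, w + 1):
            word = _window_word(tokens, i + k)
            feats.add(f"W{k}={word}")
            feats.add(f"WL{k}={word.lower()}")
        for k in range(-w, w):
            feats.add(f"WB{k}={_window_word(tokens, i + k)}|{_window_word(tokens, i + k + 1)}")
        for k in range(-w, w - 1):
            feats.add(
                f"WT{k}={_window_word(tokens, i + k)}|"
                f"{_window_word(tokens, i + k + 1)}|{_window_word(tokens, i + k + 2)}"
            )

    has_pos = any(t.pos is not None for t in tokens)
    if config.use_pos and has_pos:
        for k in range(-w, w + 1):
            feats.add(f"P{k}={_window_pos(tokens, i + k)}")
        for k in range(-w, w):
            feats.add(f"PB{k}={_window_pos(tokens, i + k)}|{_window_pos(tokens, i + k + 1)}")
        for k in range(-w, w - 1):
            feats.add(
                f"PT{k}={_window_pos(tokens, i + k)}|"
                f"{_window_pos(tokens, i + k + 1)}|{_window_pos(tokens, i + k + 2)}"
            )

    surface = tokens[i].surface
    if config.use_pattern:
        full, collapsed = word_pattern(surface)
        feats.add(f"PAT={full}")
        feats.add(f"PATC={collapsed}")
    if config.use_affixes:
        prefixes, suffixes = affixes(surface, config.affix_m)
        feats.update(f"PRE{len(p)}={p}" for p in prefixes)
        feats.update(f"SUF{len(s)}={s}" for s in suffixes)
    if config.use_ngrams:
        feats.update(f"NG={g}" for g in char_ngrams(surface, config.ngram_n))
    if config.use_chemical_affixes and resources.affix_lexicon is not None:
        matches = chemical_affixes(surface, resources.affix_lexicon)
        if "prefix" in matches:
            feats.add(f"CHEMPRE={matches['prefix']}")
        if "suffix" in matches:
            feats.add(f"CHEMSUF={matches['suffix']}")
    if config.use_gene_lexicon and resources.gene_lexicon is not None:
        if surface in resources.gene_lexicon:
            feats.add("GENE=1")
    if config.use_semantic and resources.semantic_lexicon is not None:
        tags = lexicon_annotate(tokens, resources.semantic_lexicon)
        for k in range(-w, w + 1):
            if 0 <= i + k < len(tags) and tags[i + k] is not None:
                feats.add(f"SEM{k}={tags[i + k]}")
    feats |= representation_features(surface, resources, config, i)
    return frozenset(feats)


def extract_sentence(
    tokens: Sequence[Token],
    resources: Resources | None = None,
    config: FeatureConfig | None = None,
) -> list[frozenset[str]]:
    """Feature sets for every position of one sentence."""
    return [assemble(tokens, i, resources, config) for i in range(len(tokens))]
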