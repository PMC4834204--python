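"""Seeded synthetic patent corpora with planted chemical mentions.

Real challenge corpora of annotated medicinal-chemistry patents are not
redistributable, so every pipeline stage is exercised on generated data
instead.  A small morpheme grammar emits pseudo-chemical names —
``prefix (infix)* suffix`` concatenations such as "benzoxyamine", optionally
preceded by a digit/comma/hyphen locant block ("1,6-") and optionally
followed by a structure word ("... acid") that belongs to the gold span.
Documents mix these names into sentences of common background words, with
gene-symbol decoys planted as confusable negatives.  Exact character offsets
of every planted mention are recorded as gold annotations, and matched
resources (affix lexicon, gene lexicon, structure-word lexicon, embedding
matrix) are derived from the same inventories.

What this emulates: the offset bookkeeping, orthographic shape and lexical
cues of patent chemical mentions.  What it does not: real patent syntax,
nested or discontinuous mentions, and genuinely ambiguous chemistry — so a
model that is perfect here is only known to be correct mechanically, not
chemically.

All randomness flows from one integer seed through a single NumPy generator;
identical seeds give byte-identical corpora.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus_io import (
    ENTITY_TYPES,
    EntityAnnotation,
    PatentDocument,
    write_abstracts,
    write_annotations,
)
from .embeddings import EmbeddingMatrix
from .preprocess import split_sentences, tokenize

DEFAULT_PREFIXES = (
    "benz", "meth", "eth", "prop", "but", "chlor", "fluor", "brom",
    "cycl", "hydr", "sulf", "nitr", "phen", "acet", "carb", "oxal",
)
DEFAULT_INFIXES = ("oxy", "yl", "ox", "amino", "meth", "eno", "azo", "ace")
DEFAULT_SUFFIXES = (
    "ol", "one", "ate", "ide", "ine", "amine", "oxide", "ane", "ene",
    "ylic", "onic", "amide",
)
DEFAULT_STRUCTURE_WORDS = ("acid", "compound", "derivative", "ester", "salt")
_COMMON_WORDS = (
    "the", "invention", "relates", "to", "a", "novel", "method", "for",
    "treatment", "of", "disease", "in", "patients", "with", "improved",
    "activity", "and", "stability", "wherein", "said", "composition",
    "comprises", "an", "effective", "amount", "useful", "as", "agent",
    "against", "present", "provides", "preparation", "process", "thereof",
    "such", "compositions", "are", "described", "herein", "use", "by",
    "administration", "or", "formulation", "dosage", "form", "is",
    "disclosed", "also", "new", "this", "may", "be", "used", "more",
    "particularly", "relating", "their", "various", "other", "suitable",
)


def _pseudo_background(n: int = 700, seed: int = 12) -> tuple[str, ...]:
    """Open-vocabulary filler: pseudo-words from non-chemical syllables.

    Patent prose has a long-tailed vocabulary; with only a closed handful of
    function words a labeler could shortcut to "unseen word = chemical".
    Hundreds of distinct pseudo-words keep unknown background words common,
    so chemical mentions must be recognized by their form, not their novelty.
    Uses the stdlib RNG, whose stream is stable across library versions.
    """
    import random as _random

    syllables = (
        "ta", "re", "mo", "li", "sa", "du", "ke", "vi", "po", "nu",
        "wa", "fe", "ga", "se", "ro", "ti", "la", "me",
    )
    rng = _random.Random(seed)
    words = {
        "".join(rng.choice(syllables) for _ in range(rng.randint(2, 4)))
        for _ in range(n)
    }
    return tuple(sorted(words))


DEFAULT_BACKGROUND = _COMMON_WORDS + _pseudo_background()

#: relative mention-type frequencies mirroring an annotated patent corpus
#: (family and systematic names dominant, identifiers rare)
DEFAULT_TYPE_MIX = {
    "ABBREVIATION": 0.014,
    "FAMILY": 0.365,
    "FORMULA": 0.066,
    "IDENTIFIER": 0.004,
    "MULTIPLE": 0.005,
    "SYSTEMATIC": 0.287,
    "TRIVIAL": 0.259,
}


@dataclass(frozen=True)
class GrammarConfig:
    """Generator settings; defaults are the reference study conditions."""

    chem_prefixes: tuple[str, ...] = DEFAULT_PREFIXES
    chem_infixes: tuple[str, ...] = DEFAULT_INFIXES
    chem_suffixes: tuple[str, ...] = DEFAULT_SUFFIXES
    structure_words: tuple[str, ...] = DEFAULT_STRUCTURE_WORDS
    background_vocab: tuple[str, ...] = DEFAULT_BACKGROUND
    n_documents: int = 100
    sentences_per_doc: tuple[int, int] = (2, 5)
    tokens_per_sentence: tuple[int, int] = (6, 14)
    entity_rate: float = 1.0
    locant_rate: float = 0.3
    structure_attach_rate: float = 0.2
    gene_decoy_rate: float = 0.08
    n_gene_decoys: int = 20
    char_noise_rate: float = 0.0
    truncate_rate: float = 0.0
    type_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_MIX)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.chem_prefixes and self.chem_suffixes and self.background_vocab):
            raise ValueError("morpheme inventories and background vocab must be non-empty")
        if self.entity_rate < 0:
            raise ValueError("entity_rate must be >= 0")
        total = sum(self.type_mix.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"type_mix sums to {total}, expected 1")


@dataclass
class SyntheticCorpus:
    documents: list[PatentDocument]
    annotations: list[EntityAnnotation]
    affix_lexicon: frozenset[str]
    gene_lexicon: frozenset[str]
    structure_lexicon: frozenset[str]
    config: GrammarConfig
    seed: int


def _make_gene_decoys(rng: np.random.Generator, n: int) -> list[str]:
    letters = np.array(list("ABCDEFGHKLMNPRSTVW"))
    decoys = []
    for _ in range(n):
        length = int(rng.integers(2, 5))
        name = "".join(rng.choice(letters, size=length)) + str(int(rng.integers(1, 10)))
        decoys.append(name)
    return sorted(set(decoys))


def _chemical_name(rng: np.random.Generator, cfg: GrammarConfig) -> str:
    """One grammar-derived name: prefix (infix)* suffix, possibly noised."""
    parts = [str(rng.choice(cfg.chem_prefixes))]
    for _ in range(int(rng.integers(0, 3))):
        parts.append(str(rng.choice(cfg.chem_infixes)))
    parts.append(str(rng.choice(cfg.chem_suffixes)))
    name = "".join(parts)
    if cfg.char_noise_rate and rng.random() < cfg.char_noise_rate and len(name) > 2:
        # corrupt the surface form: each interior letter flips with prob 1/4,
        # degrading affix and n-gram cues while embeddings still know the word
        chars = list(name)
        for pos in range(1, len(chars) - 1):
            if rng.random() < 0.25:
                chars[pos] = chr(ord("a") + int(rng.integers(0, 26)))
        name = "".join(chars)
    return name


def _locant(rng: np.random.Generator) -> str:
    digits = [str(int(rng.integers(1, 10))) for _ in range(int(rng.integers(1, 3)))]
    return ",".join(digits) + "-"


@dataclass
class _PlannedEntity:
    text: str       # surface placed in the running text
    gold_len: int   # gold span length (may exclude a truncated tail)
    etype: str


def _plan_entity(rng: np.random.Generator, cfg: GrammarConfig) -> _PlannedEntity:
    name = _chemical_name(rng, cfg)
    if rng.random() < cfg.locant_rate:
        name = _locant(rng) + name
    text = name
    gold_len = len(name)
    if cfg.structure_words and rng.random() < cfg.structure_attach_rate:
        tail = str(rng.choice(cfg.structure_words))
        text = f"{name} {tail}"
        gold_len = len(text)
        if cfg.truncate_rate and rng.random() < cfg.truncate_rate:
            gold_len = len(name)  # gold omits the tail: a merge-rule target
    types = sorted(cfg.type_mix)
    probs = np.array([cfg.type_mix[t] for t in types])
    etype = str(rng.choice(types, p=probs / probs.sum()))
    return _PlannedEntity(text, gold_len, etype)


def _build_section(
    rng: np.random.Generator,
    cfg: GrammarConfig,
    n_sentences: int,
    decoys: Sequence[str],
) -> tuple[str, list[tuple[int, int, str, str]]]:
    """Assemble one section; returns (text, [(start, end, surface, type)])."""
    parts: list[str] = []
    spans: list[tuple[int, int, str, str]] = []
    cursor = 0

    def emit(fragment: str) -> None:
        nonlocal cursor
        parts.append(fragment)
        cursor += len(fragment)

    for s in range(n_sentences):
        if s > 0:
            emit(" ")
        n_background = int(rng.integers(*cfg.tokens_per_sentence))
        words = [str(w) for w in rng.choice(cfg.background_vocab, size=n_background)]
        words[0] = words[0].capitalize()
        if decoys and cfg.gene_decoy_rate and rng.random() < cfg.gene_decoy_rate * n_background:
            slot = int(rng.integers(1, n_background))
            words[slot] = str(rng.choice(decoys))
        n_entities = int(rng.poisson(cfg.entity_rate))
        # entity slots: after word k, for k in 1..n_background-1 (never first)
        slots = sorted(
            int(x) for x in rng.choice(
                np.arange(1, n_background), size=min(n_entities, n_background - 1),
                replace=False,
            )
        ) if n_entities else []
        entities = {slot: _plan_entity(rng, cfg) for slot in slots}
        for k, word in enumerate(words):
            if k > 0:
                emit(" ")
            emit(word)
            if k in entities:
                ent = entities[k]
                emit(" ")
                start = cursor
                emit(ent.text)
                spans.append(
                    (start, start + ent.gold_len, ent.text[: ent.gold_len], ent.etype)
                )
        emit(".")
    return "".join(parts), spans


def generate_corpus(config: GrammarConfig | None = None) -> SyntheticCorpus:
    """Generate documents, exact-offset gold annotations and matched lexicons."""
    cfg = config or GrammarConfig()
    rng = np.random.default_rng(cfg.seed)
    decoys = _make_gene_decoys(rng, cfg.n_gene_decoys)
    documents: list[PatentDocument] = []
    annotations: list[EntityAnnotation] = []
    for d in range(cfg.n_documents):
        doc_id = f"SYN{d:05d}"
        title, title_spans = _build_section(rng, cfg, 1, decoys)
        n_sent = int(rng.integers(cfg.sentences_per_doc[0], cfg.sentences_per_doc[1] + 1))
        abstract, abs_spans = _build_section(rng, cfg, n_sent, decoys)
        documents.append(PatentDocument(doc_id, title, abstract))
        for section, spans in (("T", title_spans), ("A", abs_spans)):
            for start, end, surface, etype in spans:
                annotations.append(
                    EntityAnnotation(doc_id, section, start, end, surface, etype, 1.0)
                )
    morphemes = frozenset(
        m.lower()
        for m in (cfg.chem_prefixes + cfg.chem_infixes + cfg.chem_suffixes)
    )
    return SyntheticCorpus(
        documents=documents,
        annotations=annotations,
        affix_lexicon=morphemes,
        gene_lexicon=frozenset(decoys),
        structure_lexicon=frozenset(cfg.structure_words),
        config=cfg,
        seed=cfg.seed,
    )


def generate_lexicons(
    corpus: SyntheticCorpus,
) -> tuple[frozenset[str], frozenset[str], frozenset[str]]:
    """(affix, gene, structure-word) lexicons matched to a generated corpus."""
    return corpus.affix_lexicon, corpus.gene_lexicon, corpus.structure_lexicon


def corpus_token_vocab(documents: Sequence[PatentDocument]) -> set[str]:
    """All lowercased token surfaces over titles and abstracts."""
    vocab: set[str] = set()
    for doc in documents:
        for text in (doc.title, doc.abstract):
            for span in split_sentences(text):
                vocab.update(t.surface.lower() for t in tokenize(text, span))
    return vocab


def chemical_token_vocab(corpus: SyntheticCorpus) -> set[str]:
    """Lowercased alphabetic tokens occurring inside gold mention spans."""
    chems: set[str] = set()
    for ann in corpus.annotations:
        for tok in tokenize(ann.text):
            if any(c.isalpha() for c in tok.surface):
                chems.add(tok.surface.lower())
    return chems


def generate_embeddings(
    vocab: Sequence[str],
    chemical_words: set[str],
    dim: int = 10,
    seed: int = 0,
) -> EmbeddingMatrix:
    """Planted-signal embedding matrix: dimension 0 separates chemical words.

    Chemical words load strongly positive on dimension 0 (mean 2.0); all
    words get small centered noise everywhere else, so binarization recovers
    a '+' on the signal dimension for (almost) exactly the chemical subset.
    """
    if dim < 2:
        raise ValueError("dim must be >= 2")
    rng = np.random.default_rng(seed)
    words = sorted(set(vocab))
    values = rng.normal(0.0, 0.1, size=(len(words), dim))
    for i, word in enumerate(words):
        if word in chemical_words:
            values[i, 0] = rng.normal(2.0, 0.2)
    return EmbeddingMatrix(words, values)


def write_corpus_files(corpus: SyntheticCorpus, outdir: str | Path) -> dict[str, Path]:
    """Write the corpus in the standard file dialects plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "abstracts": outdir / "abstracts.tsv",
        "gold": outdir / "gold.tsv",
        "affix_lexicon": outdir / "affix_lexicon.txt",
        "gene_lexicon": outdir / "gene_lexicon.txt",
        "structure_lexicon": outdir / "structure_lexicon.txt",
        "manifest": outdir / "manifest.txt",
    }
    write_abstracts(corpus.documents, paths["abstracts"])
    write_annotations(corpus.annotations, paths["gold"])
    for key, entries in (
        ("affix_lexicon", corpus.affix_lexicon),
        ("gene_lexicon", corpus.gene_lexicon),
        ("structure_lexicon", corpus.structure_lexicon),
    ):
        with open(paths[key], "w", encoding="utf-8") as handle:
            for entry in sorted(entries):
                handle.write(entry + "\n")
    cfg = corpus.config
    with open(paths["manifest"], "w", encoding="utf-8") as handle:
        handle.write(f"seed\t{corpus.seed}\n")
        handle.write(f"n_documents\t{cfg.n_documents}\n")
        handle.write(f"entity_rate\t{cfg.entity_rate}\n")
        handle.write(f"char_noise_rate\t{cfg.char_noise_rate}\n")
        handle.write(f"truncate_rate\t{cfg.truncate_rate}\n")
    return paths
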