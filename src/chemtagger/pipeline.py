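"""End-to-end glue: documents -> features -> model -> mentions -> passages.

This is the orchestration layer the command-line interface and the tests
drive: sentence-split and tokenize each section, extract feature sets,
train or decode the sequence model, realign BIO labels to character offsets,
apply the post-processing rules and derive passage predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Sequence

from . import features as F
from . import tagger
from .corpus_io import EntityAnnotation, PatentDocument
from .postprocess import StructureWordLexicon, derive_cpd, postprocess
from .preprocess import (
    LabeledSequence,
    decode_bio,
    encode_bio,
    split_sentences,
    tokenize,
)


@dataclass
class SentenceRef:
    """A tokenized sentence anchored to its document and section."""

    doc_id: str
    section: str
    tokens: list
    text: str


def iter_sentences(documents: Sequence[PatentDocument]) -> list[SentenceRef]:
    refs: list[SentenceRef] = []
    for doc in documents:
        for section in ("T", "A"):
            text = doc.section_text(section)
            for span in split_sentences(text):
                toks = tokenize(text, span)
                if toks:
                    refs.append(SentenceRef(doc.doc_id, section, toks, text))
    return refs


def training_sequences(
    documents: Sequence[PatentDocument],
    annotations: Sequence[EntityAnnotation],
    resources: F.Resources | None = None,
    config: F.FeatureConfig | None = None,
) -> list[tagger.TrainingSequence]:
    """(feature sets, BIO labels) for every sentence of the corpus."""
    by_section: dict[tuple[str, str], list[EntityAnnotation]] = {}
    for ann in annotations:
        by_section.setdefault((ann.doc_id, ann.section), []).append(ann)
    data: list[tagger.TrainingSequence] = []
    for ref in iter_sentences(documents):
        anns = [
            a
            for a in by_section.get((ref.doc_id, ref.section), [])
            if a.start < ref.tokens[-1].end and a.end > ref.tokens[0].start
        ]
        labeled = encode_bio(ref.tokens, anns)
        feats = F.extract_sentence(ref.tokens, resources, config)
        data.append((feats, labeled.labels))
    return data


def _entity_confidence(
    feats: list[frozenset[str]],
    labels: list[str],
    span: tuple[int, int],
    model: tagger.SequenceModel,
) -> float:
    """Monotone margin-based confidence in [0, 1).

    The margin is the score drop from relabeling the entity's tokens as O;
    it is non-negative because the decoded path is the argmax.  Mapped
    through m / (1 + m) so large margins saturate towards 1.
    """
    alt = list(labels)
    for i in range(span[0], span[1]):
        alt[i] = "O"
    margin = tagger.sequence_score(feats, labels, model) - tagger.sequence_score(
        feats, alt, model
    )
    margin = max(margin, 0.0)
    return margin / (1.0 + margin)


def tag_documents(
    documents: Sequence[PatentDocument],
    model: tagger.SequenceModel,
    resources: F.Resources | None = None,
    config: F.FeatureConfig | None = None,
    decode=None,
) -> list[EntityAnnotation]:
    """Decode every sentence and realign predictions to character offsets."""
    decode = decode or tagger.viterbi
    predictions: list[EntityAnnotation] = []
    for ref in iter_sentences(documents):
        feats = F.extract_sentence(ref.tokens, resources, config)
        labels = decode(feats, model)
        seq = LabeledSequence(ref.tokens, list(labels))
        # token index spans of each decoded entity, for the margin confidence
        spans: list[tuple[int, int]] = []
        start = None
        for i, lab in enumerate(labels):
            if lab == "B":
                if start is not None:
                    spans.append((start, i))
                start = i
            elif lab == "O":
                if start is not None:
                    spans.append((start, i))
                    start = None
            elif lab == "I" and start is None:
                start = i  # repaired downstream by decode_bio
        if start is not None:
            spans.append((start, len(labels)))
        anns = decode_bio(seq, ref.doc_id, ref.section, ref.text)
        for ann, span in zip(anns, spans):
            conf = _entity_confidence(feats, list(labels), span, model)
            predictions.append(dc_replace(ann, confidence=conf))
    return predictions


@dataclass
class PipelineResult:
    predictions: list[EntityAnnotation]
    section_predictions: list


def run(
    documents: Sequence[PatentDocument],
    model: tagger.SequenceModel,
    resources: F.Resources | None = None,
    config: F.FeatureConfig | None = None,
    structure_lexicon: StructureWordLexicon | None = None,
    apply_postprocess: bool = True,
) -> PipelineResult:
    """Tag, post-process and derive passage predictions for a corpus."""
    preds = tag_documents(documents, model, resources, config)
    if apply_postprocess:
        preds = postprocess(documents, preds, structure_lexicon)
    return PipelineResult(preds, derive_cpd(documents, preds))
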