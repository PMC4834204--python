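"""Corpus, annotation and prediction file I/O.

All dialects are plain UTF-8 TSV without headers:

* abstracts: ``doc_id<TAB>title<TAB>abstract``
* gold annotations: ``doc_id<TAB>section<TAB>start<TAB>end<TAB>text<TAB>type``
  (an optional 7th confidence column is accepted; gold rows default to 1.0)
* mention-level (CEMP) predictions: ``doc_id:section:start:end<TAB>rank<TAB>confidence``
* passage-level (CPD) predictions: ``doc_id_section<TAB>rank<TAB>confidence``

Offsets are 0-based, end-exclusive, counted in Unicode code points, so the
annotated surface always equals ``section_text[start:end]``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

ENTITY_TYPES = (
    "ABBREVIATION",
    "FAMILY",
    "FORMULA",
    "IDENTIFIER",
    "MULTIPLE",
    "SYSTEMATIC",
    "TRIVIAL",
)
UNKNOWN_TYPE = "UNKNOWN"
SECTIONS = ("T", "A")


class CorpusError(ValueError):
    """Malformed corpus, annotation or prediction input."""


@dataclass(frozen=True)
class PatentDocument:
    """One patent record: a title and an abstract keyed by document id."""

    doc_id: str
    title: str
    abstract: str

    def section_text(self, section: str) -> str:
        if section == "T":
            return self.title
        if section == "A":
            return self.abstract
        raise CorpusError(f"unknown section {section!r} (expected 'T' or 'A')")


@dataclass(frozen=True, order=True)
class EntityAnnotation:
    """An offset-anchored chemical mention, gold or predicted."""

    doc_id: str
    section: str
    start: int
    end: int
    text: str
    entity_type: str = UNKNOWN_TYPE
    confidence: float = 1.0
    rank: int | None = field(default=None, compare=False)

    def key(self) -> tuple[str, str, int, int]:
        """Strict-match identity: document, section and both offsets."""
        return (self.doc_id, self.section, self.start, self.end)


@dataclass(frozen=True)
class CorpusStats:
    per_type: dict[str, int]
    total: int


def _split_line(line: str, n_fields: int, lineno: int, path: str) -> list[str]:
    fields = line.split("\t")
    if len(fields) != n_fields:
        raise CorpusError(
            f"{path}:{lineno}: expected {n_fields} tab-separated fields, "
            f"got {len(fields)}"
        )
    return fields


def read_abstracts(path: str | Path) -> list[PatentDocument]:
    """Read a 3-column abstracts file; one document per non-empty line."""
    docs: list[PatentDocument] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            doc_id, title, abstract = _split_line(line, 3, lineno, str(path))
            if not doc_id:
                raise CorpusError(f"{path}:{lineno}: empty doc_id")
            if doc_id in seen:
                raise CorpusError(f"{path}:{lineno}: duplicate doc_id {doc_id!r}")
            seen.add(doc_id)
            docs.append(PatentDocument(doc_id, title, abstract))
    return docs


def write_abstracts(docs: Iterable[PatentDocument], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for doc in docs:
            handle.write(f"{doc.doc_id}\t{doc.title}\t{doc.abstract}\n")


def validate_annotation(ann: EntityAnnotation, doc: PatentDocument) -> None:
    """Enforce the substring invariant against the referenced section."""
    text = doc.section_text(ann.section)
    if not (0 <= ann.start < ann.end <= len(text)):
        raise CorpusError(
            f"{ann.doc_id}: offsets [{ann.start}, {ann.end}) out of range for "
            f"section {ann.section} of length {len(text)}"
        )
    actual = text[ann.start : ann.end]
    if actual != ann.text:
        raise CorpusError(
            f"{ann.doc_id}: annotation text {ann.text!r} does not match "
            f"section substring {actual!r} at [{ann.start}, {ann.end})"
        )
    if not 0.0 <= ann.confidence <= 1.0:
        raise CorpusError(f"{ann.doc_id}: confidence {ann.confidence} outside [0, 1]")


def read_annotations(
    path: str | Path, corpus: Sequence[PatentDocument]
) -> list[EntityAnnotation]:
    """Read gold/predicted annotations and validate offsets against *corpus*."""
    by_id = {doc.doc_id: doc for doc in corpus}
    anns: list[EntityAnnotation] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) not in (6, 7):
                raise CorpusError(
                    f"{path}:{lineno}: expected 6 or 7 fields, got {len(fields)}"
                )
            doc_id, section, start_s, end_s, text, etype = fields[:6]
            confidence = float(fields[6]) if len(fields) == 7 else 1.0
            if doc_id not in by_id:
                raise CorpusError(f"{path}:{lineno}: unknown doc_id {doc_id!r}")
            if etype not in ENTITY_TYPES and etype != UNKNOWN_TYPE:
                raise CorpusError(f"{path}:{lineno}: unknown entity type {etype!r}")
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise CorpusError(f"{path}:{lineno}: non-integer offset") from exc
            ann = EntityAnnotation(doc_id, section, start, end, text, etype, confidence)
            validate_annotation(ann, by_id[doc_id])
            anns.append(ann)
    return anns


def write_annotations(anns: Iterable[EntityAnnotation], path: str | Path) -> None:
    """Write the 7-column annotation dialect (with confidence)."""
    with open(path, "w", encoding="utf-8") as handle:
        for ann in anns:
            handle.write(
                f"{ann.doc_id}\t{ann.section}\t{ann.start}\t{ann.end}\t"
                f"{ann.text}\t{ann.entity_type}\t{format_confidence(ann.confidence)}\n"
            )


def format_confidence(value: float) -> str:
    """Up to 6 decimals, trailing zeros trimmed; '0.9' not '0.900000'."""
    out = f"{value:.6f}".rstrip("0")
    if out.endswith("."):
        out += "0"
    return out


def assign_ranks(preds: Iterable[EntityAnnotation]) -> list[EntityAnnotation]:
    """Rank 1..N per document by descending confidence, ties by (section, start)."""
    ranked: list[EntityAnnotation] = []
    by_doc: dict[str, list[EntityAnnotation]] = {}
    for pred in preds:
        by_doc.setdefault(pred.doc_id, []).append(pred)
    for doc_id in sorted(by_doc):
        doc_preds = sorted(
            by_doc[doc_id], key=lambda a: (-a.confidence, a.section, a.start, a.end)
        )
        for rank, pred in enumerate(doc_preds, start=1):
            ranked.append(replace(pred, rank=rank))
    return ranked


def write_cemp_predictions(
    preds: Iterable[EntityAnnotation], path: str | Path
) -> None:
    """Write mention predictions as ``doc:sec:start:end<TAB>rank<TAB>conf``."""
    with open(path, "w", encoding="utf-8") as handle:
        for pred in assign_ranks(preds):
            handle.write(
                f"{pred.doc_id}:{pred.section}:{pred.start}:{pred.end}"
                f"\t{pred.rank}\t{format_confidence(pred.confidence)}\n"
            )


def write_cpd_predictions(
    section_preds: Iterable[tuple[str, str, float]], path: str | Path
) -> None:
    """Write passage predictions, globally ranked by descending confidence.

    *section_preds* yields ``(doc_id, section, confidence)`` triples; ties are
    broken by doc_id then section.
    """
    ordered = sorted(section_preds, key=lambda p: (-p[2], p[0], p[1]))
    with open(path, "w", encoding="utf-8") as handle:
        for rank, (doc_id, section, conf) in enumerate(ordered, start=1):
            handle.write(f"{doc_id}_{section}\t{rank}\t{format_confidence(conf)}\n")


def corpus_statistics(annotations: Iterable[EntityAnnotation]) -> CorpusStats:
    """Per-type mention counts over the seven annotation types plus total."""
    counts = Counter(ann.entity_type for ann in annotations)
    per_type = {etype: counts.get(etype, 0) for etype in ENTITY_TYPES}
    if UNKNOWN_TYPE in counts:
        per_type[UNKNOWN_TYPE] = counts[UNKNOWN_TYPE]
    return CorpusStats(per_type=per_type, total=sum(per_type.values()))
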