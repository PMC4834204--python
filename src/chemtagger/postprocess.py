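"""Rule-based post-processing of recognized mentions and passage derivation.

Three heuristics clean up the statistical tagger's output:

1. **Propagation** — every recognized surface becomes a dictionary entry and
   all of its other exact, word-bounded occurrences in the same document are
   labeled too (a classifier that found "aspirin" once should find it twice).
2. **Structure-word merging** — a mention directly preceded or followed by a
   chemical-structure word ("acid", "chiral", "compound"...) is extended to
   include it, fixing partially recognized names such as "Chiral tricyclic".
3. **Bracket filtering** — a mention whose surface has unmatched parentheses
   or square brackets (e.g. "(S-1-P") is a truncation artifact and is dropped.

Passage-level (CPD) output is derived from mention-level (CEMP) output: each
title/abstract section is scored with the maximum confidence of the mentions
recognized inside it, or 0 when none.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .corpus_io import EntityAnnotation, PatentDocument, validate_annotation


@dataclass(frozen=True)
class SectionPrediction:
    doc_id: str
    section: str
    confidence: float


class StructureWordLexicon:
    """Words indicating chemical structure, matched case-insensitively."""

    def __init__(self, words: Iterable[str]) -> None:
        self.words = frozenset(w.lower() for w in words if w)

    def __contains__(self, word: str) -> bool:
        return word.lower() in self.words


def _is_word_char(ch: str) -> bool:
    return ch.isalnum()


def propagate_exact_matches(
    documents: Sequence[PatentDocument],
    predictions: Sequence[EntityAnnotation],
) -> list[EntityAnnotation]:
    """Add unlabeled exact occurrences of every predicted surface.

    Matching is case-sensitive and word-bounded: an occurrence must be
    flanked by non-alphanumeric characters or the string edges, so "pirin"
    never fires inside "aspirin".  New mentions inherit the type and
    confidence of the highest-confidence source with the same surface and
    never overlap an existing prediction.
    """
    out = list(predictions)
    by_doc: dict[str, list[EntityAnnotation]] = {}
    for pred in predictions:
        by_doc.setdefault(pred.doc_id, []).append(pred)
    for doc in documents:
        doc_preds = by_doc.get(doc.doc_id, [])
        if not doc_preds:
            continue
        sources: dict[str, EntityAnnotation] = {}
        for pred in sorted(doc_preds, key=lambda p: -p.confidence):
            sources.setdefault(pred.text, pred)
        occupied: dict[str, list[tuple[int, int]]] = {"T": [], "A": []}
        for pred in doc_preds:
            occupied[pred.section].append((pred.start, pred.end))
        for section in ("T", "A"):
            text = doc.section_text(section)
            for surface, source in sources.items():
                start = 0
                while True:
                    idx = text.find(surface, start)
                    if idx == -1:
                        break
                    end = idx + len(surface)
                    start = idx + 1
                    left_ok = idx == 0 or not _is_word_char(text[idx - 1])
                    right_ok = end == len(text) or not _is_word_char(text[end])
                    if not (left_ok and right_ok):
                        continue
                    if any(s < end and e > idx for s, e in occupied[section]):
                        continue
                    occupied[section].append((idx, end))
                    out.append(
                        EntityAnnotation(
                            doc.doc_id,
                            section,
                            idx,
                            end,
                            surface,
                            source.entity_type,
                            source.confidence,
                        )
                    )
    return out


def is_balanced(surface: str) -> bool:
    """Bracket-matching scan over ( ) and [ ]; braces and others ignored."""
    stack: list[str] = []
    pairs = {")": "(", "]": "["}
    for ch in surface:
        if ch in "([":
            stack.append(ch)
        elif ch in ")]":
            if not stack or stack[-1] != pairs[ch]:
                return False
            stack.pop()
    return not stack


def remove_unbalanced(
    predictions: Sequence[EntityAnnotation],
) -> list[EntityAnnotation]:
    """Drop mentions whose surface has unmatched ( ) or [ ]."""
    return [p for p in predictions if is_balanced(p.text)]


def _adjacent_word(
    text: str, pos: int, direction: int
) -> tuple[int, int] | None:
    """The alphanumeric word just before (direction -1) or after (+1) *pos*,
    separated only by whitespace or a hyphen; None when absent."""
    i = pos + (direction if direction < 0 else 0)
    # skip the separator (at most whitespace run or one hyphen)
    sep_seen = False
    while 0 <= i < len(text) and (text[i].isspace() or text[i] == "-"):
        i += direction
        sep_seen = True
    if not sep_seen:
        return None
    if not (0 <= i < len(text)) or not _is_word_char(text[i]):
        return None
    j = i
    while 0 <= j < len(text) and _is_word_char(text[j]):
        j += direction
    if direction < 0:
        return (j + 1, i + 1)
    return (i, j)


def merge_structure_words(
    documents: Sequence[PatentDocument],
    predictions: Sequence[EntityAnnotation],
    lexicon: StructureWordLexicon,
    max_passes: int = 3,
) -> list[EntityAnnotation]:
    """Extend mentions over adjacent structure words, to a fixpoint.

    The word immediately before or after a mention (across whitespace or a
    hyphen) is absorbed when it is in the lexicon; up to *max_passes* sweeps
    so chained modifiers resolve, e.g. "... carboxylic acid".
    """
    by_id = {doc.doc_id: doc for doc in documents}
    current = list(predictions)
    for _ in range(max_passes):
        changed = False
        merged: list[EntityAnnotation] = []
        seen: set[tuple[str, str, int, int]] = set()
        for pred in current:
            doc = by_id.get(pred.doc_id)
            if doc is None:
                merged.append(pred)
                continue
            text = doc.section_text(pred.section)
            start, end = pred.start, pred.end
            before = _adjacent_word(text, start, -1)
            if before is not None and text[before[0] : before[1]] in lexicon:
                start = before[0]
            after = _adjacent_word(text, end, +1)
            if after is not None and text[after[0] : after[1]] in lexicon:
                end = after[1]
            if (start, end) != (pred.start, pred.end):
                changed = True
                pred = replace(
                    pred, start=start, end=end, text=text[start:end]
                )
            key = pred.key()
            if key not in seen:
                seen.add(key)
                merged.append(pred)
        current = merged
        if not changed:
            break
    return current


def postprocess(
    documents: Sequence[PatentDocument],
    predictions: Sequence[EntityAnnotation],
    structure_lexicon: StructureWordLexicon | None = None,
    propagate: bool = True,
    merge: bool = True,
    filter_unbalanced: bool = True,
) -> list[EntityAnnotation]:
    """Apply the rules in order propagate -> merge -> bracket filter.

    Propagation runs first so copied mentions are also eligible for merging;
    the bracket filter runs last so it cleans every produced surface.  Each
    surviving annotation is re-validated against its document.
    """
    by_id = {doc.doc_id: doc for doc in documents}
    preds = list(predictions)
    if propagate:
        preds = propagate_exact_matches(documents, preds)
    if merge and structure_lexicon is not None:
        preds = merge_structure_words(documents, preds, structure_lexicon)
    if filter_unbalanced:
        preds = remove_unbalanced(preds)
    deduped: dict[tuple[str, str, int, int], EntityAnnotation] = {}
    for pred in preds:
        key = pred.key()
        if key not in deduped or pred.confidence > deduped[key].confidence:
            deduped[key] = pred
    result = sorted(deduped.values())
    for pred in result:
        validate_annotation(pred, by_id[pred.doc_id])
    return result


def derive_cpd(
    documents: Sequence[PatentDocument],
    predictions: Sequence[EntityAnnotation],
) -> list[SectionPrediction]:
    """One prediction per (document, section): max mention confidence or 0.

    The returned list is ranked by descending confidence, ties broken by
    doc_id then section, and always has exactly 2 x |documents| entries.
    """
    best: dict[tuple[str, str], float] = {
        (doc.doc_id, section): 0.0 for doc in documents for section in ("T", "A")
    }
    for pred in predictions:
        key = (pred.doc_id, pred.section)
        if key in best:
            best[key] = max(best[key], pred.confidence)
    ordered = sorted(best.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1]))
    return [SectionPrediction(d, s, c) for (d, s), c in ordered]
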