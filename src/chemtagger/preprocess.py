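"""Sentence segmentation, offset-tracking tokenization and the BIO codec.

Chemical names make naive tokenization hazardous: locants ("1,6-"), hyphens
and brackets are part of the mention, so every split must preserve exact
character offsets into the original section text.  The rule-based tokenizer
splits on whitespace and then isolates a fixed set of punctuation characters
as single-character tokens, e.g.::

    "1,6-naphthyridonecarboxylic acid"
        -> 1 , 6 - naphthyridonecarboxylic acid

which carries the BIO labels ``B I I I I I`` for the full mention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .corpus_io import UNKNOWN_TYPE, EntityAnnotation

#: Punctuation isolated as single-character tokens; alphanumeric runs stay intact.
SPLIT_PUNCT = frozenset(",.;:()[]{}-/+=")

#: Sentence terminators.
TERMINATORS = frozenset(".!?")

_OPEN = {"(": ")", "[": "]", "{": "}"}
_CLOSE = {v: k for k, v in _OPEN.items()}

BIO_LABELS = ("O", "B", "I")


class BoundaryMismatchWarning(UserWarning):
    """An annotation boundary fell strictly inside a token."""


@dataclass(frozen=True)
class Token:
    surface: str
    start: int
    end: int
    pos: str | None = None


@dataclass
class LabeledSequence:
    """Tokens of one sentence with one B/I/O label per token."""

    tokens: list[Token]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.labels):
            raise ValueError("tokens and labels differ in length")
        for label in self.labels:
            if label not in BIO_LABELS:
                raise ValueError(f"invalid BIO label {label!r}")
        for prev, cur in zip(self.tokens, self.tokens[1:]):
            if cur.start < prev.end:
                raise ValueError("token spans overlap or are out of order")


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Return ordered, trimmed (start, end) sentence spans.

    A terminator (. ! ?) ends a sentence when followed by whitespace and then
    an uppercase letter or digit, except when the period closes a decimal
    number or a single-letter abbreviation, or when any bracket opened earlier
    in the sentence is still unclosed.
    """
    spans: list[tuple[int, int]] = []
    n = len(text)
    sent_start = 0
    depth = 0
    i = 0
    while i < n:
        ch = text[i]
        if ch in _OPEN:
            depth += 1
        elif ch in _CLOSE and depth > 0:
            depth -= 1
        elif ch in TERMINATORS and depth == 0:
            j = i + 1
            if j < n and text[j].isspace():
                while j < n and text[j].isspace():
                    j += 1
                next_ok = j < n and (text[j].isupper() or text[j].isdigit())
                abbrev = (
                    ch == "."
                    and i >= 1
                    and text[i - 1].isalpha()
                    and (i == 1 or not text[i - 2].isalnum())
                )
                if next_ok and not abbrev:
                    spans.append((sent_start, i + 1))
                    sent_start = j
                    i = j
                    depth = 0
                    continue
            elif j == n:
                break
        i += 1
    if sent_start < n:
        spans.append((sent_start, n))
    return [_trim(text, s, e) for s, e in spans if text[s:e].strip()]


def _trim(text: str, start: int, end: int) -> tuple[int, int]:
    while start < end and text[start].isspace():
        start += 1
    while end > start and text[end - 1].isspace():
        end -= 1
    return (start, end)


def tokenize(
    text: str, span: tuple[int, int] | None = None
) -> list[Token]:
    """Tokenize ``text[span]``; offsets are into *text* itself.

    Whitespace separates tokens; each character in :data:`SPLIT_PUNCT`
    becomes its own token; maximal runs of all other characters stay intact.
    """
    start, end = span if span is not None else (0, len(text))
    tokens: list[Token] = []
    i = start
    while i < end:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch in SPLIT_PUNCT:
            tokens.append(Token(ch, i, i + 1))
            i += 1
            continue
        j = i
        while j < end and not text[j].isspace() and text[j] not in SPLIT_PUNCT:
            j += 1
        tokens.append(Token(text[i:j], i, j))
        i = j
    return tokens


def encode_bio(
    tokens: Sequence[Token], annotations: Iterable[EntityAnnotation]
) -> LabeledSequence:
    """Label each token B/I/O against offset-anchored annotations.

    The first token overlapping an annotation gets B, later overlapping tokens
    of the same annotation get I.  An annotation boundary strictly inside a
    token raises :class:`BoundaryMismatchWarning` and the annotation is
    expanded outward to the token boundaries.
    """
    labels = ["O"] * len(tokens)
    for ann in sorted(annotations, key=lambda a: (a.start, a.end)):
        overlapping = [
            idx
            for idx, tok in enumerate(tokens)
            if tok.start < ann.end and tok.end > ann.start
        ]
        if not overlapping:
            continue
        first, last = tokens[overlapping[0]], tokens[overlapping[-1]]
        if first.start < ann.start or last.end > ann.end:
            warnings.warn(
                f"annotation [{ann.start}, {ann.end}) {ann.text!r} crosses token "
                f"boundaries; expanded to [{first.start}, {last.end})",
                BoundaryMismatchWarning,
                stacklevel=2,
            )
        labels[overlapping[0]] = "B"
        for idx in overlapping[1:]:
            labels[idx] = "I"
    return LabeledSequence(list(tokens), labels)


def decode_bio(
    sequence: LabeledSequence,
    doc_id: str = "",
    section: str = "A",
    text: str | None = None,
    confidence: float = 1.0,
) -> list[EntityAnnotation]:
    """Realign a label sequence back to character-offset annotations.

    Maximal runs ``B I*`` become one annotation from the first token's start
    to the last token's end.  An ``I`` with no preceding ``B``/``I`` is
    repaired to ``B`` (with a warning) rather than dropped.
    """
    anns: list[EntityAnnotation] = []
    run: list[Token] = []

    def flush() -> None:
        if run:
            start, end = run[0].start, run[-1].end
            surface = (
                text[start:end]
                if text is not None
                else _join_surfaces(run)
            )
            anns.append(
                EntityAnnotation(
                    doc_id, section, start, end, surface, UNKNOWN_TYPE, confidence
                )
            )
            run.clear()

    prev = "O"
    for tok, label in zip(sequence.tokens, sequence.labels):
        if label == "I" and prev == "O":
            warnings.warn(
                f"label I without preceding B at offset {tok.start}; repaired to B",
                UserWarning,
                stacklevel=2,
            )
            label = "B"
        if label == "B":
            flush()
            run.append(tok)
        elif label == "I":
            run.append(tok)
        else:
            flush()
        prev = label
    flush()
    return anns


def _join_surfaces(run: Sequence[Token]) -> str:
    parts = [run[0].surface]
    for prev, cur in zip(run, run[1:]):
        parts.append(" " * (cur.start - prev.end))
        parts.append(cur.surface)
    return "".join(parts)


def write_conll(
    sequences: Iterable[LabeledSequence], path: str | Path
) -> None:
    """Token-per-line interchange: surface, start, end, label[, pos]."""
    with open(path, "w", encoding="utf-8") as handle:
        for seq in sequences:
            for tok, label in zip(seq.tokens, seq.labels):
                fields = [tok.surface, str(tok.start), str(tok.end), label]
                if tok.pos is not None:
                    fields.append(tok.pos)
                handle.write("\t".join(fields) + "\n")
            handle.write("\n")


def read_conll(path: str | Path) -> list[LabeledSequence]:
    sequences: list[LabeledSequence] = []
    tokens: list[Token] = []
    labels: list[str] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line:
                if tokens:
                    sequences.append(LabeledSequence(tokens, labels))
                    tokens, labels = [], []
                continue
            fields = line.split("\t")
            if len(fields) not in (4, 5):
                raise ValueError(f"{path}:{lineno}: expected 4 or 5 fields")
            surface, start, end, label = fields[:4]
            pos = fields[4] if len(fields) == 5 else None
            tokens.append(Token(surface, int(start), int(end), pos))
            labels.append(label)
    if tokens:
        sequences.append(LabeledSequence(tokens, labels))
    return sequences
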