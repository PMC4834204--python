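"""Binarized word embeddings.

Real-valued word vectors are discretized per dimension into the three symbols
``+``, ``-`` and ``0``: for column *j* of the V x D embedding matrix M, the
positive mean MEAN(j)+ is the mean of the strictly positive entries and the
negative mean MEAN(j)- the mean of the strictly negative entries; then

    M*[i, j] = '+'  if M[i, j] >  MEAN(j)+
               '-'  if M[i, j] <  MEAN(j)-
               '0'  otherwise.

Only dimensions carrying an unusually strong signal survive as non-zero
symbols, which turns a dense vector into a handful of sparse, discrete
features suitable for a linear sequence labeler.  A column with no positive
(resp. negative) entries gets a +inf (resp. -inf) threshold so no cell can
cross it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass
class EmbeddingMatrix:
    vocab: list[str]
    values: np.ndarray  # V x D, float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.vocab):
            raise ValueError("matrix shape does not match vocabulary")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("embedding matrix contains non-finite values")


@dataclass
class ColumnMeans:
    mean_pos: np.ndarray
    mean_neg: np.ndarray
    n_pos: np.ndarray
    n_neg: np.ndarray


@dataclass
class BinarizedEmbedding:
    vocab: list[str]
    symbols: np.ndarray  # V x D over {'+', '-', '0'}

    def row(self, word: str) -> np.ndarray | None:
        try:
            idx = self.vocab.index(word)
        except ValueError:
            return None
        return self.symbols[idx]

    _index: dict[str, int] | None = None

    def lookup(self, word: str) -> np.ndarray | None:
        """Dict-backed row lookup (built lazily; vocab must not mutate)."""
        if self._index is None:
            self._index = {w: i for i, w in enumerate(self.vocab)}
        idx = self._index.get(word)
        return None if idx is None else self.symbols[idx]


def read_embedding_matrix(path: str | Path) -> EmbeddingMatrix:
    """Read word-per-line text vectors: ``word v1 v2 ... vD``.

    An optional leading header line ``V D`` (two integers) is tolerated.
    Duplicate words keep the last row, with a warning.
    """
    vocab: list[str] = []
    rows: list[list[float]] = []
    index: dict[str, int] = {}
    dim: int | None = None
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            fields = raw.split()
            if not fields:
                continue
            if lineno == 1 and len(fields) == 2:
                try:
                    int(fields[0]), int(fields[1])
                    continue  # header line
                except ValueError:
                    pass
            word, vals = fields[0], fields[1:]
            try:
                row = [float(v) for v in vals]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value") from exc
            if dim is None:
                dim = len(row)
                if dim == 0:
                    raise ValueError(f"{path}:{lineno}: no vector values")
            elif len(row) != dim:
                raise ValueError(
                    f"{path}:{lineno}: expected {dim} values, got {len(row)}"
                )
            if word in index:
                warnings.warn(
                    f"duplicate word {word!r} at {path}:{lineno}; last wins",
                    UserWarning,
                    stacklevel=2,
                )
                rows[index[word]] = row
            else:
                index[word] = len(vocab)
                vocab.append(word)
                rows.append(row)
    return EmbeddingMatrix(vocab, np.array(rows, dtype=float).reshape(len(vocab), dim or 0))


def column_means(matrix: EmbeddingMatrix | np.ndarray) -> ColumnMeans:
    """Per-dimension means of the strictly positive and strictly negative entries."""
    values = matrix.values if isinstance(matrix, EmbeddingMatrix) else np.asarray(matrix, float)
    pos_mask = values > 0
    neg_mask = values < 0
    n_pos = pos_mask.sum(axis=0)
    n_neg = neg_mask.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean_pos = np.where(
            n_pos > 0,
            np.where(pos_mask, values, 0.0).sum(axis=0) / np.maximum(n_pos, 1),
            np.inf,
        )
        mean_neg = np.where(
            n_neg > 0,
            np.where(neg_mask, values, 0.0).sum(axis=0) / np.maximum(n_neg, 1),
            -np.inf,
        )
    return ColumnMeans(mean_pos, mean_neg, n_pos, n_neg)


def binarize(matrix: EmbeddingMatrix) -> BinarizedEmbedding:
    """Discretize the matrix into {+, -, 0} with strict-inequality thresholds."""
    means = column_means(matrix)
    values = matrix.values
    symbols = np.full(values.shape, "0", dtype="<U1")
    symbols[values > means.mean_pos] = "+"
    symbols[values < means.mean_neg] = "-"
    return BinarizedEmbedding(list(matrix.vocab), symbols)


def write_binarized(emb: BinarizedEmbedding, path: str | Path) -> None:
    """One line per word: ``word<TAB>s1s2...sD`` with symbols in {+,-,0}."""
    with open(path, "w", encoding="utf-8") as handle:
        for word, row in zip(emb.vocab, emb.symbols):
            handle.write(f"{word}\t{''.join(row)}\n")


def read_binarized(path: str | Path) -> BinarizedEmbedding:
    vocab: list[str] = []
    rows: list[list[str]] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            word, _, syms = line.partition("\t")
            if not syms or set(syms) - {"+", "-", "0"}:
                raise ValueError(f"{path}:{lineno}: malformed symbol string")
            vocab.append(word)
            rows.append(list(syms))
    return BinarizedEmbedding(vocab, np.array(rows, dtype="<U1"))
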