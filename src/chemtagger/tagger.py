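"""Linear-chain BIO sequence labeling.

The model is a sparse linear chain: a sequence (y_1..y_n) over the labels
(O, B, I) scores

    score(x, y) = sum_i sum_{f in F_i} w_em(f, y_i)  +  sum_i w_tr(y_{i-1}, y_i)

with a distinguished START state for i = 1.  Decoding is exact Viterbi over
the 3-label chain; among equally scoring paths the lexicographically smallest
one under the label order O < B < I is returned, compared position by
position, which makes decoding fully deterministic.

Training is an averaged structured perceptron: decode each training sequence
with the current weights and, on a mistake, add the gold feature counts and
subtract the predicted ones.  The returned model averages the weight vector
over all update steps, the standard variance-reduction trick for perceptrons.
The trainer/decoder pair is pluggable: anything exposing the same
``fit(data, config)`` / ``decode(features, model)`` contract can stand in
(e.g. an external CRF toolkit) without touching the rest of the pipeline.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

LABELS = ("O", "B", "I")
START = "<START>"

_MODEL_HEADER = "chemtagger-model v1"


@dataclass
class SequenceModel:
    """Sparse emission and transition weights; absent keys read as 0."""

    emission: dict[tuple[str, str], float] = field(default_factory=dict)
    transition: dict[tuple[str, str], float] = field(default_factory=dict)
    labels: tuple[str, ...] = LABELS


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 10
    seed: int = 0
    shuffle: bool = True
    averaging: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


TrainingSequence = tuple[Sequence[frozenset[str]], Sequence[str]]


def sequence_score(
    features: Sequence[frozenset[str]],
    labels: Sequence[str],
    model: SequenceModel,
) -> float:
    """Linear-chain score of one (features, labels) pair."""
    if len(features) != len(labels):
        raise ValueError("features and labels differ in length")
    for label in labels:
        if label not in model.labels:
            raise ValueError(f"unknown label {label!r}")
    total = 0.0
    prev = START
    for feats, label in zip(features, labels):
        for f in feats:
            total += model.emission.get((f, label), 0.0)
        total += model.transition.get((prev, label), 0.0)
        prev = label
    return total


def _emission_scores(
    feats: frozenset[str], model: SequenceModel
) -> dict[str, float]:
    scores = dict.fromkeys(model.labels, 0.0)
    for f in feats:
        for label in model.labels:
            w = model.emission.get((f, label))
            if w:
                scores[label] += w
    return scores


def viterbi(
    features: Sequence[frozenset[str]], model: SequenceModel
) -> list[str]:
    """Exact argmax label sequence; lexicographic-min tie-break over O < B < I.

    A backward max-suffix pass followed by a greedy forward walk returns, of
    all maximizing paths, the one whose label string is smallest in the fixed
    label order — the all-O path for an all-zero model.
    """
    n = len(features)
    if n == 0:
        raise ValueError("cannot decode an empty sequence")
    labels = model.labels
    emit = [_emission_scores(f, model) for f in features]

    # suffix[i][y] = best score of positions i+1..n-1 given y at position i
    suffix = [dict.fromkeys(labels, 0.0) for _ in range(n)]
    for i in range(n - 2, -1, -1):
        for y in labels:
            suffix[i][y] = max(
                emit[i + 1][y2]
                + model.transition.get((y, y2), 0.0)
                + suffix[i + 1][y2]
                for y2 in labels
            )

    path: list[str] = []
    prev = START
    for i in range(n):
        best_label = None
        best_score = -float("inf")
        for y in labels:  # label order = tie-break order
            s = emit[i][y] + model.transition.get((prev, y), 0.0) + suffix[i][y]
            if s > best_score:
                best_score, best_label = s, y
        assert best_label is not None
        path.append(best_label)
        prev = best_label
    return path


def _feature_counts(
    features: Sequence[frozenset[str]], labels: Sequence[str]
) -> tuple[dict[tuple[str, str], int], dict[tuple[str, str], int]]:
    em: dict[tuple[str, str], int] = {}
    tr: dict[tuple[str, str], int] = {}
    prev = START
    for feats, label in zip(features, labels):
        for f in feats:
            key = (f, label)
            em[key] = em.get(key, 0) + 1
        tkey = (prev, label)
        tr[tkey] = tr.get(tkey, 0) + 1
        prev = label
    return em, tr


def train(
    data: Sequence[TrainingSequence],
    config: TrainConfig | None = None,
) -> SequenceModel:
    """Averaged structured perceptron over BIO sequences.

    Deterministic given ``config.seed``: shuffling uses its own RNG and the
    update order fully determines the weights.
    """
    if not data:
        raise ValueError("no training data")
    config = config or TrainConfig()
    model = SequenceModel()
    # lazy averaging: u accumulates step-weighted updates; avg = w - u / T
    u_em: dict[tuple[str, str], float] = {}
    u_tr: dict[tuple[str, str], float] = {}
    rng = random.Random(config.seed)
    order = list(range(len(data)))
    step = 0
    for _epoch in range(config.epochs):
        if config.shuffle:
            rng.shuffle(order)
        for idx in order:
            features, gold = data[idx]
            pred = viterbi(features, model)
            if list(pred) != list(gold):
                gold_em, gold_tr = _feature_counts(features, gold)
                pred_em, pred_tr = _feature_counts(features, pred)
                for key in set(gold_em) | set(pred_em):
                    delta = gold_em.get(key, 0) - pred_em.get(key, 0)
                    if delta:
                        model.emission[key] = model.emission.get(key, 0.0) + delta
                        u_em[key] = u_em.get(key, 0.0) + step * delta
                for key in set(gold_tr) | set(pred_tr):
                    delta = gold_tr.get(key, 0) - pred_tr.get(key, 0)
                    if delta:
                        model.transition[key] = model.transition.get(key, 0.0) + delta
                        u_tr[key] = u_tr.get(key, 0.0) + step * delta
            step += 1
    if config.averaging and step > 0:
        emission = {
            key: w - u_em.get(key, 0.0) / step for key, w in model.emission.items()
        }
        transition = {
            key: w - u_tr.get(key, 0.0) / step for key, w in model.transition.items()
        }
        model = SequenceModel(emission, transition)
    return model


# ---------------------------------------------------------------------------
# pluggable backend contract


@dataclass(frozen=True)
class Backend:
    """A trainer/decoder pair honoring the linear-chain contract."""

    fit: Callable[[Sequence[TrainingSequence], TrainConfig], SequenceModel]
    decode: Callable[[Sequence[frozenset[str]], SequenceModel], list[str]]


PERCEPTRON = Backend(fit=lambda data, cfg: train(data, cfg), decode=viterbi)

BACKENDS: dict[str, Backend] = {"perceptron": PERCEPTRON}


# ---------------------------------------------------------------------------
# serialization


def save_model(model: SequenceModel, path: str | Path) -> None:
    """Versioned key-value text: E/T rows of (feature|prev, label, weight)."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(_MODEL_HEADER + "\n")
        handle.write("labels\t" + "\t".join(model.labels) + "\n")
        for (f, label), w in sorted(model.emission.items()):
            handle.write(f"E\t{f}\t{label}\t{w!r}\n")
        for (prev, label), w in sorted(model.transition.items()):
            handle.write(f"T\t{prev}\t{label}\t{w!r}\n")


def load_model(path: str | Path) -> SequenceModel:
    with open(path, encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n")
        if header != _MODEL_HEADER:
            raise ValueError(f"{path}: not a model file (bad header {header!r})")
        labels_line = handle.readline().rstrip("\n").split("\t")
        if labels_line[0] != "labels" or len(labels_line) < 2:
            raise ValueError(f"{path}: missing labels line")
        labels = tuple(labels_line[1:])
        emission: dict[tuple[str, str], float] = {}
        transition: dict[tuple[str, str], float] = {}
        for lineno, raw in enumerate(handle, start=3):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4 or fields[0] not in ("E", "T"):
                raise ValueError(f"{path}:{lineno}: malformed model row")
            kind, key, label, w = fields
            target = emission if kind == "E" else transition
            target[(key, label)] = float(w)
    return SequenceModel(emission, transition, labels)
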