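"""Official-style evaluation: strict mention-level and passage-level metrics.

Mention-level (CEMP) scoring is strict micro-averaged: a predicted mention is
a true positive only when its document, section, start and end all equal a
gold mention's; precision, recall and F-measure are pooled over all
documents.  By default the entity type is not compared (the strict protocol
scores offsets); type-sensitive matching is available behind a flag.

Passage-level (CPD) scoring treats every title/abstract section as a binary
instance.  Thresholded metrics come from the confusion matrix (sensitivity,
specificity, accuracy, Matthews correlation coefficient); ranking metrics
walk the full descending-confidence list: AUC_PR is the average precision
sum_k P(k) * dR(k) (step interpolation), and P_full_R is the precision at
the smallest depth where recall first reaches 1.  All rates are reported as
percentages except AUC_PR, which stays on the [0, 1] scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .corpus_io import EntityAnnotation
from .postprocess import SectionPrediction


@dataclass(frozen=True)
class CempReport:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_measure: float


@dataclass(frozen=True)
class CpdReport:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float
    p_full_r: float
    auc_pr: float


def _ratio(num: float, den: float) -> float:
    return 100.0 * num / den if den else 0.0


def evaluate_cemp(
    gold: Iterable[EntityAnnotation],
    predicted: Iterable[EntityAnnotation],
    match_type: bool = False,
) -> CempReport:
    """Strict micro-averaged precision/recall/F over exact offset matches."""

    def key(ann: EntityAnnotation):
        base = ann.key()
        return base + (ann.entity_type,) if match_type else base

    gold_keys = {key(g) for g in gold}
    pred_keys: set = set()
    for pred in predicted:
        k = key(pred)
        if k in pred_keys:
            raise ValueError(f"duplicate prediction {k}")
        pred_keys.add(k)
    tp = len(gold_keys & pred_keys)
    fp = len(pred_keys - gold_keys)
    fn = len(gold_keys - pred_keys)
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return CempReport(tp, fp, fn, precision, recall, f)


def mcc_percent(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient on the percentage scale."""
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return 100.0 * (tp * tn - fp * fn) / math.sqrt(denom)


def evaluate_cpd(
    gold_positive: Iterable[tuple[str, str]],
    predictions: Sequence[SectionPrediction],
    threshold: float = 0.0,
) -> CpdReport:
    """Confusion-matrix and ranking metrics over all emitted sections.

    *gold_positive* lists the (doc_id, section) pairs that truly contain a
    chemical; *predictions* must cover every section of the corpus (the
    exhaustive ranking), each predicted positive iff confidence > threshold.
    """
    gold = set(gold_positive)
    emitted = {(p.doc_id, p.section) for p in predictions}
    missing = gold - emitted
    if missing:
        raise ValueError(f"gold sections missing from predictions: {sorted(missing)[:5]}")
    tp = fp = tn = fn = 0
    for pred in predictions:
        positive = pred.confidence > threshold
        is_gold = (pred.doc_id, pred.section) in gold
        if positive and is_gold:
            tp += 1
        elif positive:
            fp += 1
        elif is_gold:
            fn += 1
        else:
            tn += 1
    sensitivity = _ratio(tp, tp + fn)
    specificity = _ratio(tn, tn + fp)
    accuracy = _ratio(tp + tn, tp + fp + tn + fn)
    auc_pr, p_full_r, _ = pr_ranking_metrics(gold, predictions)
    return CpdReport(
        tp,
        fp,
        tn,
        fn,
        sensitivity,
        specificity,
        accuracy,
        mcc_percent(tp, fp, tn, fn),
        p_full_r,
        auc_pr,
    )


def pr_ranking_metrics(
    gold_positive: Iterable[tuple[str, str]],
    ranked: Sequence[SectionPrediction],
) -> tuple[float, float, list[tuple[float, float]]]:
    """(AUC_PR, P_full_R %, PR curve points) of a full descending ranking.

    Walks the list top-down recording (recall, precision) after every item;
    AUC_PR is the average precision sum_k P(k) * dR(k); P_full_R is the
    precision at the first depth where recall reaches 1.0.
    """
    gold = set(gold_positive)
    if not gold:
        raise ValueError("no gold-positive sections")
    n_pos = len(gold)
    curve: list[tuple[float, float]] = []
    tp = 0
    auc = 0.0
    p_full_r = 0.0
    prev_recall = 0.0
    for depth, pred in enumerate(ranked, start=1):
        if (pred.doc_id, pred.section) in gold:
            tp += 1
        recall = tp / n_pos
        precision = tp / depth
        curve.append((recall, precision))
        auc += precision * (recall - prev_recall)
        if recall == 1.0 and prev_recall < 1.0:
            p_full_r = 100.0 * precision
        prev_recall = recall
    return auc, p_full_r, curve


def format_cemp(report: CempReport) -> str:
    return (
        f"tp\t{report.tp}\nfp\t{report.fp}\nfn\t{report.fn}\n"
        f"precision\t{report.precision:.2f}\nrecall\t{report.recall:.2f}\n"
        f"f_measure\t{report.f_measure:.2f}\n"
    )


def format_cpd(report: CpdReport) -> str:
    return (
        f"tp\t{report.tp}\nfp\t{report.fp}\ntn\t{report.tn}\nfn\t{report.fn}\n"
        f"sensitivity\t{report.sensitivity:.2f}\nspecificity\t{report.specificity:.2f}\n"
        f"accuracy\t{report.accuracy:.2f}\nmcc\t{report.mcc:.2f}\n"
        f"p_full_r\t{report.p_full_r:.2f}\nauc_pr\t{report.auc_pr:.4f}\n"
    )


def write_report(text: str, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(text)
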