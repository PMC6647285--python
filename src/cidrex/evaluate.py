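"""Merge intra- and inter-level predictions and score document-level pairs.

Positive predictions from both levels are unioned on the
(doc id, chemical id, disease id) triple; when both levels predict the same
pair the higher score (and its source) wins.  Scoring is exact set matching of
id triples with the standard zero conventions for empty denominators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .corpus import DocPrediction

__all__ = ["EvalResult", "PRCurve", "merge_predictions", "evaluate_prf", "pr_curve"]

Triple = tuple[str, str, str]


@dataclass(frozen=True)
class EvalResult:
    true_positives: int
    false_positives: int
    false_negatives: int
    precision: float
    recall: float
    f1: float


@dataclass(frozen=True)
class PRCurve:
    """(threshold, precision, recall) triples at strictly increasing thresholds."""

    points: list[tuple[float, float, float]]


def merge_predictions(
    intra_preds: Iterable[DocPrediction],
    inter_preds: Iterable[DocPrediction],
    threshold: float = 0.5,
) -> list[DocPrediction]:
    """Union the positive predictions of both levels, keeping the higher score.

    A prediction is positive when its score is >= ``threshold``; pass 0 to keep
    every scored pair (useful for precision-recall sweeps).
    """
    best: dict[Triple, DocPrediction] = {}
    for p in list(intra_preds) + list(inter_preds):
        if p.score < threshold:
            continue
        cur = best.get(p.triple)
        if cur is None or p.score > cur.score:
            best[p.triple] = p
    return sorted(best.values(), key=lambda p: (p.doc_id, -p.score, p.chemical_id, p.disease_id))


def _prf(tp: int, fp: int, fn: int) -> EvalResult:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return EvalResult(tp, fp, fn, precision, recall, f1)


def evaluate_prf(
    predicted: Iterable[Triple | DocPrediction], gold: Iterable[Triple]
) -> EvalResult:
    """Precision / recall / F1 by exact matching of (doc, chemical, disease) triples."""
    pred_set = {p.triple if isinstance(p, DocPrediction) else tuple(p) for p in predicted}
    gold_set = {tuple(g) for g in gold}
    tp = len(pred_set & gold_set)
    return _prf(tp, len(pred_set - gold_set), len(gold_set - pred_set))


def pr_curve(
    predictions: Sequence[DocPrediction],
    gold: Iterable[Triple],
    n_thresholds: int = 50,
) -> PRCurve:
    """Sweep score thresholds and evaluate the pairs scoring at or above each.

    Thresholds are the distinct prediction scores, thinned to at most
    ``n_thresholds`` evenly spaced quantiles.  Recall is non-increasing along
    the sweep because the prediction sets are nested.
    """
    gold_set = {tuple(g) for g in gold}
    scores = sorted({p.score for p in predictions})
    if len(scores) > n_thresholds:
        qs = np.linspace(0, len(scores) - 1, n_thresholds).round().astype(int)
        scores = sorted({scores[i] for i in qs})
    points = []
    for t in scores:
        kept = [p for p in predictions if p.score >= t]
        res = evaluate_prf(kept, gold_set)
        points.append((t, res.precision, res.recall))
    return PRCurve(points)
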