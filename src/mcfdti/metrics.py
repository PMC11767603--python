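"""Ranking and threshold classification metrics.

These are authored directly from their definitions — AUC as the Mann–Whitney
pair statistic (ties count one half) and AUPR as tie-grouped average precision
— and are checked in the test suite against independent brute-force oracles
and against scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


def _validate(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError(
            f"labels and scores differ in length: {labels.shape} vs {scores.shape}")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return labels.astype(int), scores


def auc(labels, scores) -> float:
    """Area under the ROC curve via the Mann–Whitney statistic.

    Equals the fraction of (positive, negative) pairs ranked correctly, with
    ties counting 0.5.
    """
    labels, scores = _validate(labels, scores)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes to be present")
    ranks = rankdata(scores)  # average ranks over ties
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def aupr(labels, scores) -> float:
    """Area under the precision–recall curve as tie-grouped average precision.

    Scores are swept from high to low; at each distinct score the precision is
    evaluated on the full tie group and weighted by the recall increment.
    """
    labels, scores = _validate(labels, scores)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("AUPR requires at least one positive")
    order = np.argsort(-scores, kind="stable")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    # indices where a tie group ends
    boundaries = np.flatnonzero(np.diff(sorted_scores)) + 1
    ends = np.append(boundaries, labels.size)
    tp = np.cumsum(sorted_labels)[ends - 1]
    precision = tp / ends
    recall_increment = np.diff(np.concatenate(([0], tp))) / n_pos
    return float(np.sum(precision * recall_increment))


@dataclass
class ThresholdMetrics:
    accuracy: float
    precision: float
    recall: float
    precision_defined: bool = True


def threshold_metrics(labels, scores, threshold: float = 0.5) -> ThresholdMetrics:
    """Accuracy/precision/recall at a decision threshold (score >= threshold).

    Precision is reported as 0 with ``precision_defined=False`` when nothing
    is predicted positive.
    """
    labels, scores = _validate(labels, scores)
    preds = (scores >= threshold).astype(int)
    tp = int(((preds == 1) & (labels == 1)).sum())
    fp = int(((preds == 1) & (labels == 0)).sum())
    fn = int(((preds == 0) & (labels == 1)).sum())
    accuracy = float((preds == labels).mean())
    if tp + fp == 0:
        precision, defined = 0.0, False
    else:
        precision, defined = tp / (tp + fp), True
    recall = 0.0 if tp + fn == 0 else tp / (tp + fn)
    return ThresholdMetrics(accuracy, float(precision), float(recall), defined)
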