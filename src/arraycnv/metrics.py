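"""Evaluation statistics: AUC (Mann-Whitney form), Brier score,
confusion-matrix accuracy and Jaccard set similarity."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

__all__ = ["compute_auc", "brier_score", "confusion_accuracy", "jaccard_similarity"]


def compute_auc(labels, scores) -> float:
    """Area under the ROC curve via the Mann-Whitney U statistic.

    Equals the probability that a uniformly drawn positive outranks a
    uniformly drawn negative, with ties counted 1/2.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have the same length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)  # midranks handle ties
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def brier_score(labels, scores) -> float:
    """Mean squared difference between predicted probability and label."""
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("scores must lie in [0, 1]")
    return float(np.mean((scores - labels) ** 2))


def confusion_accuracy(tp: int, tn: int, fp: int, fn: int) -> float:
    """(tp + tn) / total from confusion-matrix counts."""
    counts = (tp, tn, fp, fn)
    if any(c < 0 for c in counts):
        raise ValueError("confusion counts must be >= 0")
    total = sum(counts)
    if total == 0:
        raise ValueError("confusion matrix is empty")
    return (tp + tn) / total


def jaccard_similarity(set_a, set_b) -> float:
    """|A ∩ B| / |A ∪ B| for two sets."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        raise ValueError("Jaccard similarity undefined for two empty sets")
    return len(a & b) / len(a | b)
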