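"""Final classification and evaluation: KNN (k = 5 by default), the
standard classification report (accuracy, per-class and macro
precision/recall/F1, confusion matrix), and a Wilcoxon rank-sum harness for
comparing the accuracy distributions of repeated feature-selection runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.stats import mannwhitneyu
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.neighbors import NearestNeighbors

from .errors import DegenerateTestError, GafsError, InsufficientDataError

logger = logging.getLogger(__name__)


def standardize(
    train_X: np.ndarray, *others: np.ndarray
) -> Tuple[np.ndarray, ...]:
    """Center/scale by the training mean and sd (sd 0 mapped to 1 so
    constant columns pass through). Returns the transformed train matrix
    followed by the transformed extra matrices."""
    mu = train_X.mean(axis=0)
    sd = train_X.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    out = [(train_X - mu) / sd]
    out.extend((m - mu) / sd for m in others)
    return tuple(out)


def knn_predict(
    train_X: np.ndarray,
    train_y: np.ndarray,
    query_X: np.ndarray,
    k: int = 5,
    scale: bool = True,
) -> np.ndarray:
    """Label each query row by majority vote among its k Euclidean-nearest
    training rows.

    Features are standardized by the training mean/sd by default so that
    high-variance columns do not dominate the distance. Vote ties are broken
    by the smaller mean neighbor distance, then by the lowest class index —
    the prediction is fully deterministic.
    """
    train_X = np.asarray(train_X, dtype=float)
    query_X = np.asarray(query_X, dtype=float)
    train_y = np.asarray(train_y)
    if train_X.ndim != 2 or query_X.ndim != 2:
        raise GafsError("feature matrices must be 2-D")
    if train_X.shape[1] != query_X.shape[1]:
        raise GafsError(
            f"feature-space mismatch: train has {train_X.shape[1]} columns, "
            f"query has {query_X.shape[1]}"
        )
    if train_X.shape[0] != train_y.shape[0]:
        raise GafsError("train matrix and labels disagree on sample count")
    if not 1 <= k <= train_X.shape[0]:
        raise GafsError(f"k={k} must be in [1, n_train={train_X.shape[0]}]")
    if query_X.shape[0] == 0:
        return np.empty(0, dtype=train_y.dtype)

    if scale:
        train_X, query_X = standardize(train_X, query_X)

    classes, y_idx = np.unique(train_y, return_inverse=True)
    nn = NearestNeighbors(n_neighbors=k, metric="euclidean").fit(train_X)
    dist, idx = nn.kneighbors(query_X)

    nq, nc = query_X.shape[0], classes.size
    neigh_cls = y_idx[idx]  # (nq, k)
    rows = np.repeat(np.arange(nq), k)
    counts = np.zeros((nq, nc))
    dsum = np.zeros((nq, nc))
    np.add.at(counts, (rows, neigh_cls.ravel()), 1.0)
    np.add.at(dsum, (rows, neigh_cls.ravel()), dist.ravel())

    max_count = counts.max(axis=1, keepdims=True)
    mean_dist = np.where(counts > 0, dsum / np.maximum(counts, 1.0), np.inf)
    # among max-vote classes pick the smallest mean distance; np.argmin
    # takes the lowest class index on remaining ties
    tie_key = np.where(counts == max_count, mean_dist, np.inf)
    winner = np.argmin(tie_key, axis=1)
    return classes[winner]


@dataclass
class ClassificationReport:
    """Confusion matrix (rows = true class, columns = predicted class, in
    sorted class order), overall accuracy, per-class one-vs-rest
    precision/recall/F1, and their unweighted (macro) means."""

    classes: np.ndarray
    confusion: np.ndarray
    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float

    def to_dict(self) -> dict:
        return {
            "classes": [_as_scalar(c) for c in self.classes],
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "per_class": {
                str(_as_scalar(c)): {
                    "precision": float(p),
                    "recall": float(r),
                    "f1": float(f),
                    "support": int(s),
                }
                for c, p, r, f, s in zip(
                    self.classes, self.precision, self.recall, self.f1, self.support
                )
            },
            "macro": {
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "f1": self.macro_f1,
            },
        }


def _as_scalar(x):
    return x.item() if hasattr(x, "item") else x


def evaluate(true_labels, predicted_labels) -> ClassificationReport:
    """Classification report from paired label vectors.

    Per-class metrics are one-vs-rest: precision = TP/(TP+FP),
    recall = TP/(TP+FN), F1 their harmonic mean; a class with zero
    predicted (or actual) positives gets 0 for the affected metric. The
    macro row is the unweighted mean over classes.
    """
    y_true = np.asarray(true_labels)
    y_pred = np.asarray(predicted_labels)
    if y_true.size == 0:
        raise GafsError("cannot evaluate empty label vectors")
    if y_true.shape != y_pred.shape:
        raise GafsError("label vectors must have equal length")

    classes = np.unique(np.concatenate([y_true, y_pred]))
    conf = confusion_matrix(y_true, y_pred, labels=classes)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, zero_division=0
    )
    support = conf.sum(axis=1)
    if np.any(conf.sum(axis=0) == 0) or np.any(support == 0):
        logger.warning(
            "a class has zero predicted or actual positives; affected "
            "precision/recall reported as 0"
        )
    accuracy = float(np.trace(conf) / conf.sum())
    return ClassificationReport(
        classes=classes,
        confusion=conf,
        accuracy=accuracy,
        precision=prec,
        recall=rec,
        f1=f1,
        support=support,
        macro_precision=float(prec.mean()),
        macro_recall=float(rec.mean()),
        macro_f1=float(f1.mean()),
    )


def wilcoxon_rank_sum(
    accuracies_a: Sequence[float], accuracies_b: Sequence[float]
) -> Tuple[float, float]:
    """Two-sided rank-sum test on two samples of run accuracies.

    Returns the Mann-Whitney U statistic of the first sample and the
    two-sided p-value. Uses exact enumeration for small tie-free samples
    (both n <= 8) and the midrank normal approximation otherwise. Raises
    when every observation across both samples is identical (ranks carry no
    information)."""
    a = np.asarray(accuracies_a, dtype=float)
    b = np.asarray(accuracies_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each sample needs >= 2 runs")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        raise DegenerateTestError(
            "all observations are tied across both samples; the rank-sum "
            "test is degenerate"
        )
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (max(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_runs(
    accuracies_a: Sequence[float],
    accuracies_b: Sequence[float],
    significance: float = 0.05,
) -> dict:
    """Rank-sum comparison harness: declares a significant difference when
    the two-sided p-value falls below the significance level (0.05)."""
    stat, p = wilcoxon_rank_sum(accuracies_a, accuracies_b)
    return {
        "statistic": stat,
        "p_value": p,
        "significance_level": significance,
        "significant": bool(p < significance),
    }
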