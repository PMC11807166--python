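"""Filter-based feature scoring: one-way ANOVA relevance, Pearson
redundancy, and the greedy minimum-redundancy-maximum-relevance (mRMR)
score vector that drives filter-mode chromosome fitness.

mRMR ranks features by relevance to the class label (the one-way
F-statistic for continuous features) penalized by redundancy with the
features already picked (mean absolute Pearson correlation). Features are
selected one at a time; at iteration i > 1 the score of a candidate f is

    score_i(f) = F(f, target) / (sum_{s in selected} |corr(f, s)| / (i-1))

and the maximizer joins the selected set with that score recorded. The
first pick is pure relevance. The resulting per-feature scores are what a
chromosome's fitness averages over its selected positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Optional

import numpy as np

from .datasets import FeatureDataset
from .errors import GafsError, InsufficientDataError

# Sentinel for an infinite F (zero within-class variance with a real class
# effect): large enough to outrank any finite F, finite so sorting works.
F_CAP = 1e12

# Floor for the mean-|corr| denominator when a candidate is (numerically)
# uncorrelated with everything selected so far; the quotient is undefined
# there, and a tiny floor preserves "high relevance, zero redundancy wins".
DEFAULT_DENOM_EPS = 1e-12


def f_statistic(column: np.ndarray, labels: np.ndarray) -> float:
    """One-way ANOVA F statistic of one feature column against class labels.

    Between-class mean square over within-class mean square. Conventions for
    degenerate inputs: a constant column has no class effect and returns 0;
    zero within-class variance with nonzero between-class variance would be
    infinite and is capped at ``F_CAP`` so that perfectly separating
    features rank first instead of crashing the ranking.
    """
    x = np.asarray(column, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise InsufficientDataError("need >= 2 classes present")
    if np.any(counts < 2):
        raise InsufficientDataError("every class needs >= 2 samples")

    grand = x.mean()
    ssb = 0.0
    ssw = 0.0
    for cls, n_c in zip(classes, counts):
        xc = x[labels == cls]
        mu = xc.mean()
        ssb += n_c * (mu - grand) ** 2
        ssw += np.sum((xc - mu) ** 2)

    if ssb <= 0.0:
        return 0.0
    if ssw <= 0.0:
        return F_CAP
    k, n = classes.size, x.size
    f = (ssb / (k - 1)) / (ssw / (n - k))
    return float(min(f, F_CAP))


def pearson_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson product-moment correlation; 0 by convention when either
    vector is constant (no redundancy signal)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise GafsError("inputs must be equal-length 1-D vectors of size >= 2")
    da = a - a.mean()
    db = b - b.mean()
    na = np.sqrt(np.sum(da * da))
    nb = np.sqrt(np.sum(db * db))
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.clip(np.sum(da * db) / (na * nb), -1.0, 1.0))


@dataclass
class FilterScores:
    """Per-feature mRMR scores.

    ``scores[f]`` is the mRMR score assigned at the iteration feature ``f``
    was selected; ``selection_order`` is the greedy pick order (a
    permutation of 0..d-1); ``relevance[f]`` is the raw F-statistic of
    feature ``f`` against the target.
    """

    scores: np.ndarray
    selection_order: np.ndarray
    relevance: np.ndarray

    def __post_init__(self):
        d = self.scores.shape[0]
        order = np.sort(self.selection_order)
        if not np.array_equal(order, np.arange(d)):
            raise GafsError("selection_order must be a permutation of 0..d-1")

    @property
    def n_features(self) -> int:
        return self.scores.shape[0]

    def rank_of(self) -> np.ndarray:
        """Selection rank per feature (0 = picked first)."""
        ranks = np.empty(self.n_features, dtype=int)
        ranks[self.selection_order] = np.arange(self.n_features)
        return ranks


def mrmr_score_vector(
    ds: FeatureDataset,
    split: Optional[str] = "train",
    denom_eps: float = DEFAULT_DENOM_EPS,
) -> FilterScores:
    """Greedy mRMR scoring of every feature on one split of a dataset.

    Scores are computed on the training rows by default (feature quality is
    assessed before selection; evaluation rows never enter). Ties in the
    greedy argmax are broken by the lowest feature index for determinism.
    """
    mask = ds.rows(split)
    X = ds.matrix[mask]
    y = ds.labels[mask]
    d = X.shape[1]
    if d < 2:
        raise GafsError("mRMR needs at least 2 features")

    relevance = np.array([f_statistic(X[:, j], y) for j in range(d)])

    selected: list = []
    scores = np.empty(d)
    # running sum over selected features of |corr(f, s)| for each candidate
    abs_corr_sum = np.zeros(d)
    remaining = np.ones(d, dtype=bool)

    first = int(np.argmax(relevance))  # argmax takes lowest index on ties
    selected.append(first)
    scores[first] = relevance[first]
    remaining[first] = False

    while remaining.any():
        last = selected[-1]
        cand = np.flatnonzero(remaining)
        for j in cand:
            abs_corr_sum[j] += abs(pearson_correlation(X[:, j], X[:, last]))
        denom = abs_corr_sum[cand] / len(selected)
        denom = np.maximum(denom, denom_eps)
        quotient = relevance[cand] / denom
        pick = cand[int(np.argmax(quotient))]
        scores[pick] = relevance[pick] / max(
            abs_corr_sum[pick] / len(selected), denom_eps
        )
        selected.append(int(pick))
        remaining[pick] = False

    return FilterScores(
        scores=scores,
        selection_order=np.array(selected, dtype=int),
        relevance=relevance,
    )


# Pluggable filter registry: the artifact ships a single filter (mRMR) but
# the fitness machinery looks scorers up by name so more can be registered.
FilterScorer = Callable[..., FilterScores]
FILTER_SCORERS: Dict[str, FilterScorer] = {}


def register_filter(name: str):
    def deco(fn: FilterScorer) -> FilterScorer:
        FILTER_SCORERS[name] = fn
        return fn

    return deco


register_filter("mrmr")(mrmr_score_vector)


def get_filter(name: str) -> FilterScorer:
    try:
        return FILTER_SCORERS[name]
    except KeyError:
        raise GafsError(
            f"unknown filter {name!r}; registered: {sorted(FILTER_SCORERS)}"
        ) from None
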