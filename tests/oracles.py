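"""Independent brute-force oracles used by the tests.

Deliberately written without reusing package internals: ANOVA from raw
sums of squares via scipy, correlations via numpy, the greedy loop as a
plain exhaustive re-scan, the rank-sum p-value by full enumeration. These
stay independent of the code paths they check.
"""

from itertools import combinations

import numpy as np
from scipy import stats


def anova_f(column, labels):
    groups = [column[labels == c] for c in np.unique(labels)]
    f, _ = stats.f_oneway(*groups)
    return float(f)


def mrmr_greedy_oracle(X, y, eps=1e-12):
    """Exhaustive re-implementation of the greedy quotient loop: at every
    iteration rescan all remaining features from scratch."""
    d = X.shape[1]
    relevance = np.array([anova_f(X[:, j], y) for j in range(d)])
    order = [int(np.argmax(relevance))]
    scores = {order[0]: relevance[order[0]]}
    while len(order) < d:
        best_j, best_q = None, -np.inf
        for j in range(d):
            if j in order:
                continue
            corrs = [
                abs(np.corrcoef(X[:, j], X[:, s])[0, 1]) for s in order
            ]
            denom = max(sum(corrs) / len(order), eps)
            q = relevance[j] / denom
            if q > best_q:  # strict: ties keep the lowest index
                best_q, best_j = q, j
        order.append(best_j)
        scores[best_j] = best_q
    score_vec = np.array([scores[j] for j in range(d)])
    return np.array(order), score_vec, relevance


def counting_report_oracle(y_true, y_pred):
    """Per-class one-vs-rest metrics by direct counting."""
    classes = sorted(set(y_true) | set(y_pred))
    out = {}
    n = len(y_true)
    correct = sum(t == p for t, p in zip(y_true, y_pred))
    for c in classes:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        out[c] = (prec, rec, f1)
    macro = tuple(np.mean([out[c][i] for c in classes]) for i in range(3))
    return correct / n, out, macro


def rank_sum_exact_p(a, b):
    """Two-sided p by enumerating every assignment of the pooled ranks."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1 = len(a)
    obs = ranks[:n1].sum()
    all_sums = [
        sum(ranks[list(c)]) for c in combinations(range(len(pooled)), n1)
    ]
    mean = np.mean(all_sums)
    extreme = sum(abs(s - mean) >= abs(obs - mean) - 1e-12 for s in all_sums)
    return extreme / len(all_sums)


def knn_brute_oracle(train_X, train_y, query, k):
    """Exhaustive distance sort + majority vote, ties by mean distance then
    lowest class label."""
    preds = []
    for q in query:
        d = np.sqrt(((train_X - q) ** 2).sum(axis=1))
        nn = np.argsort(d, kind="stable")[:k]
        labels = train_y[nn]
        classes = sorted(set(labels))
        counts = {c: np.sum(labels == c) for c in classes}
        best = max(counts.values())
        tied = [c for c in classes if counts[c] == best]
        if len(tied) > 1:
            mean_d = {c: d[nn][labels == c].mean() for c in tied}
            lo = min(mean_d.values())
            tied = [c for c in tied if mean_d[c] == lo]
        preds.append(min(tied))
    return np.array(preds)
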