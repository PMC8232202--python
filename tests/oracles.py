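"""Independent brute-force re-implementations used as test oracles.

Everything here is written as plain loops straight from the defining
formulas, deliberately sharing no code with the package, so agreement is
evidence of correctness rather than of shared bugs.
"""

import itertools
import math

import numpy as np


def welch_t_abs(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    den = math.sqrt(va / len(a) + vb / len(b))
    if den == 0:
        return 0.0 if a.mean() == b.mean() else math.inf
    return abs(a.mean() - b.mean()) / den


def fisher_score(a, b):
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va + vb == 0:
        return 0.0 if np.mean(a) == np.mean(b) else math.inf
    return abs(np.mean(a) - np.mean(b)) / math.sqrt(va + vb)


def hellinger_sq(m1, v1, m2, v2):
    """2·H² between N(m1, v1) and N(m2, v2)."""
    return 2.0 - 2.0 * math.sqrt(2.0 * math.sqrt(v1) * math.sqrt(v2) / (v1 + v2)) \
        * math.exp(-((m1 - m2) ** 2) / (4.0 * (v1 + v2)))


def _minmax(X):
    X = np.asarray(X, float)
    out = np.zeros_like(X)
    for j in range(X.shape[1]):
        lo, hi = X[:, j].min(), X[:, j].max()
        if hi > lo:
            out[:, j] = (X[:, j] - lo) / (hi - lo)
    return out


def _k_nearest(i, candidates, X, k):
    """k candidate indices nearest to row i, ties by ascending index."""
    d = [(float(np.sum((X[i] - X[c]) ** 2)), c) for c in candidates]
    d.sort()
    return [c for _, c in d[:k]]


def relieff_scores(X, y, k):
    """Relief (k=1) / ReliefF weight vector by exhaustive neighbor scan."""
    X = _minmax(X)
    n, p = X.shape
    s = np.zeros(p)
    for i in range(n):
        hits = [j for j in range(n) if j != i and y[j] == y[i]]
        misses = [j for j in range(n) if y[j] != y[i]]
        hit_idx = _k_nearest(i, hits, X, k)
        miss_idx = _k_nearest(i, misses, X, k)
        for j in range(p):
            s[j] -= np.mean([(X[i, j] - X[h, j]) ** 2 for h in hit_idx])
            s[j] += np.mean([(X[i, j] - X[m, j]) ** 2 for m in miss_idx])
    return s


def _ent(labels):
    n = len(labels)
    h = 0.0
    for c in (0, 1):
        f = sum(1 for v in labels if v == c) / n
        if f > 0:
            h -= f * math.log2(f)
    return h


def _gini(labels):
    n = len(labels)
    g = 1.0
    for c in (0, 1):
        g -= (sum(1 for v in labels if v == c) / n) ** 2
    return g


def best_split_info_gain(x, y):
    """Max IG over midpoints of consecutive sorted unique values."""
    xs = sorted(set(x))
    if len(xs) == 1:
        return 0.0
    parent = _ent(y)
    best = -math.inf
    for a, b in zip(xs, xs[1:]):
        thr = (a + b) / 2
        left = [yy for xx, yy in zip(x, y) if xx <= thr]
        right = [yy for xx, yy in zip(x, y) if xx > thr]
        ig = parent - (len(left) / len(y)) * _ent(left) \
            - (len(right) / len(y)) * _ent(right)
        best = max(best, ig)
    return best


def best_split_gini(x, y):
    """Min post-split Gini over midpoint thresholds."""
    xs = sorted(set(x))
    if len(xs) == 1:
        return _gini(y)
    best = math.inf
    for a, b in zip(xs, xs[1:]):
        thr = (a + b) / 2
        left = [yy for xx, yy in zip(x, y) if xx <= thr]
        right = [yy for xx, yy in zip(x, y) if xx > thr]
        g = (len(left) / len(y)) * _gini(left) \
            + (len(right) / len(y)) * _gini(right)
        best = min(best, g)
    return best


def r_value(x, y, k, theta):
    """Fraction of points whose k-NN (1-D) contains > theta opposite labels."""
    n = len(x)
    hits = 0
    for i in range(n):
        d = sorted((abs(x[i] - x[j]), j) for j in range(n) if j != i)
        nbrs = [j for _, j in d[:k]]
        if sum(1 for j in nbrs if y[j] != y[i]) > theta:
            hits += 1
    return hits / n


def kendall_tau(r1, r2):
    """Pair-counting Kendall's τ for strict rankings."""
    p = len(r1)
    num = 0
    for i, j in itertools.combinations(range(p), 2):
        num += np.sign(r1[i] - r1[j]) * np.sign(r2[i] - r2[j])
    return num / (p * (p - 1) / 2)


def footrule(r1, r2):
    return sum(abs(a - b) for a, b in zip(r1, r2))


def auc_roc_pairs(scores, labels):
    """P(score_pos > score_neg) with ties counted one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def average_precision(scores, labels):
    """Σ over positives (in score order) of precision · Δrecall."""
    order = sorted(range(len(scores)), key=lambda i: -scores[i])
    n_pos = sum(labels)
    tp = fp = 0
    ap = 0.0
    for i in order:
        if labels[i] == 1:
            tp += 1
            ap += (tp / (tp + fp)) * (1 / n_pos)
        else:
            fp += 1
    return ap
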