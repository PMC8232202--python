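"""Eight filter-based feature scorers and their importance rankings.

Each scorer assigns every feature a univariate (or, for the Relief family,
neighborhood-based) relevance score for separating the two classes:

* ``t_test`` — absolute Welch two-sample t statistic.
* ``fisher`` — |x̄1 − x̄2| / sqrt(s1² + s2²), the Fisher score.
* ``hellinger`` — squared Hellinger distance (scaled to [0, 2]) between the
  per-class Gaussians with plug-in sample moments.
* ``relief`` / ``relieff`` — iterative nearest-hit / nearest-miss weight
  updates on min-max scaled features (ReliefF averages over k neighbors).
* ``info_gain`` — information gain of the best binary split (bits).
* ``gini`` — Gini index after the best binary split (smaller = better).
* ``r_value`` — fraction of samples whose k-nearest 1-D neighborhood is
  dominated by the opposite class (an overlap measure; smaller = better).

Scores are converted to a :class:`RankList` (rank 1 = most important) with
a deterministic tie-break by ascending feature index, so every ranking is a
strict permutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .table import FeatureTable

__all__ = [
    "ScoreVector",
    "RankList",
    "FilterRanker",
    "FILTER_METHODS",
    "score_t_test",
    "score_fisher",
    "score_hellinger",
    "score_relief",
    "score_relieff",
    "score_info_gain",
    "score_gini",
    "score_r_value",
    "rank_from_scores",
    "rank_all_filters",
]

#: Fixed method order used throughout the package (and by the aggregator).
FILTER_METHODS = (
    "t_test",
    "fisher",
    "hellinger",
    "relief",
    "relieff",
    "info_gain",
    "gini",
    "r_value",
)


@dataclass(frozen=True)
class ScoreVector:
    """Per-feature scores plus the direction in which "better" points."""

    scores: np.ndarray
    orientation: str  # "larger_better" | "smaller_better"
    method_name: str

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 1:
            raise ValueError("scores must be a vector")
        if np.any(np.isnan(s)):
            raise ValueError("scores contain NaN")
        if self.orientation not in ("larger_better", "smaller_better"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        object.__setattr__(self, "scores", s)


@dataclass(frozen=True)
class RankList:
    """A strict importance ranking: ``order[0]`` is the most important feature."""

    order: np.ndarray  # permutation of feature indices, best first
    source: str = ""

    def __post_init__(self):
        order = np.asarray(self.order, dtype=np.int64)
        p = order.shape[0]
        if sorted(order.tolist()) != list(range(p)):
            raise ValueError("order must be a permutation of 0..p-1")
        object.__setattr__(self, "order", order)

    @property
    def p(self) -> int:
        return self.order.shape[0]

    @property
    def ranks(self) -> np.ndarray:
        """``ranks[j]`` = rank of feature j (1 = most important)."""
        r = np.empty(self.p, dtype=np.int64)
        r[self.order] = np.arange(1, self.p + 1)
        return r


# ---------------------------------------------------------------------------
# per-class moments
# ---------------------------------------------------------------------------

def _class_stats(tbl: FeatureTable):
    X1 = tbl.X[tbl.y == 1]
    X2 = tbl.X[tbl.y == 0]
    m1, m2 = X1.mean(axis=0), X2.mean(axis=0)
    v1, v2 = X1.var(axis=0, ddof=1), X2.var(axis=0, ddof=1)
    return m1, m2, v1, v2, X1.shape[0], X2.shape[0]


def _minmax_scale(X: np.ndarray) -> np.ndarray:
    lo = X.min(axis=0)
    rng = X.max(axis=0) - lo
    rng = np.where(rng > 0, rng, 1.0)  # constant feature -> scaled to 0
    return (X - lo) / rng


def _stable_neighbor_order(D: np.ndarray) -> np.ndarray:
    """Row-wise neighbor order by ascending distance, ties by ascending index."""
    return np.argsort(D, axis=1, kind="stable")


# ---------------------------------------------------------------------------
# scorers (core implementations)
# ---------------------------------------------------------------------------

def _t_test_scores(tbl: FeatureTable) -> np.ndarray:
    m1, m2, v1, v2, n1, n2 = _class_stats(tbl)
    num = np.abs(m1 - m2)
    den = np.sqrt(v1 / n1 + v2 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / den
    degenerate = den == 0
    if np.any(degenerate):
        warnings.warn("zero within-class variance in both classes for some features")
        t = np.where(degenerate & (num == 0), 0.0, t)
        t = np.where(degenerate & (num > 0), np.inf, t)
    return t


def _fisher_scores(tbl: FeatureTable) -> np.ndarray:
    m1, m2, v1, v2, _, _ = _class_stats(tbl)
    num = np.abs(m1 - m2)
    den = np.sqrt(v1 + v2)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = num / den
    degenerate = den == 0
    if np.any(degenerate):
        warnings.warn("both sample variances are zero for some features")
        f = np.where(degenerate & (num == 0), 0.0, f)
        f = np.where(degenerate & (num > 0), np.inf, f)
    return f


def _hellinger_scores(tbl: FeatureTable) -> np.ndarray:
    m1, m2, v1, v2, _, _ = _class_stats(tbl)
    pooled = v1 + v2
    if np.any(pooled == 0):
        j = int(np.argmax(pooled == 0))
        raise ValueError(
            f"zero pooled variance for feature {tbl.feature_names[j]!r}; "
            "the Hellinger score is undefined"
        )
    s1, s2 = np.sqrt(v1), np.sqrt(v2)
    return 2.0 - 2.0 * np.sqrt(2.0 * s1 * s2 / pooled) * np.exp(
        -((m1 - m2) ** 2) / (4.0 * pooled)
    )


def _relief_family_scores(tbl: FeatureTable, k: int, n_iter=None, rng_seed=None):
    """Shared Relief/ReliefF update loop, fully vectorized.

    Distances are Euclidean over all features after min-max scaling to
    [0, 1]; the reported scores are on the scaled data. Neighbor ties are
    broken by ascending sample index, so the result is deterministic.
    """
    X = _minmax_scale(tbl.X)
    y = tbl.y
    n = X.shape[0]
    # squared Euclidean distances (monotone in the Euclidean metric)
    sq = np.sum(X**2, axis=1)
    D = sq[:, None] + sq[None, :] - 2.0 * X @ X.T
    np.maximum(D, 0.0, out=D)
    np.fill_diagonal(D, np.inf)

    same = y[:, None] == y[None, :]
    D_hit = np.where(same, D, np.inf)
    np.fill_diagonal(D_hit, np.inf)
    D_miss = np.where(~same, D, np.inf)

    if n_iter is None or n_iter >= n:
        rows = np.arange(n)
    else:
        rng = np.random.default_rng(rng_seed)
        rows = np.sort(rng.choice(n, size=int(n_iter), replace=False))

    hit_order = _stable_neighbor_order(D_hit[rows])[:, :k]
    miss_order = _stable_neighbor_order(D_miss[rows])[:, :k]
    n_hits = np.minimum(np.bincount(y, minlength=2)[y[rows]] - 1, k)
    if np.any(n_hits < 1):
        warnings.warn("a class has a single sample; those updates are skipped")
        keep = n_hits >= 1
        rows, hit_order, miss_order = rows[keep], hit_order[keep], miss_order[keep]

    Xi = X[rows][:, None, :]                      # (m, 1, p)
    hit_terms = (Xi - X[hit_order]) ** 2          # (m, k, p)
    miss_terms = (Xi - X[miss_order]) ** 2
    return (miss_terms.mean(axis=1) - hit_terms.mean(axis=1)).sum(axis=0)


def _entropy2(pos, neg):
    """Binary entropy in bits of a (pos, neg) count split; 0·log0 = 0."""
    tot = np.maximum(pos + neg, 1)

    def plogp(f):
        out = np.zeros_like(np.asarray(f, dtype=float))
        np.log2(f, out=out, where=np.asarray(f) > 0)
        return np.asarray(f) * out

    return -(plogp(pos / tot) + plogp(neg / tot))


def _gini2(pos, neg):
    tot = np.maximum(pos + neg, 1)
    return 1.0 - (pos / tot) ** 2 - (neg / tot) ** 2


def _best_split_scores(tbl: FeatureTable, criterion: str) -> np.ndarray:
    """Best binary-threshold split per feature.

    Thresholds are the midpoints of consecutive sorted unique values;
    ``criterion='info_gain'`` maximizes the gain, ``criterion='gini'``
    minimizes the post-split Gini index. Constant features get the
    degenerate value (0 gain / parent Gini).
    """
    X, y = tbl.X, tbl.y
    n, p = X.shape
    n_pos = int(y.sum())
    parent_ent = float(_entropy2(np.array(n_pos), np.array(n - n_pos)))
    parent_gini = float(_gini2(np.array(n_pos), np.array(n - n_pos)))
    out = np.empty(p)
    for j in range(p):
        x = X[:, j]
        order = np.argsort(x, kind="stable")
        xs, ys = x[order], y[order]
        cut = np.nonzero(xs[1:] > xs[:-1])[0]  # split after position i
        if cut.size == 0:
            out[j] = 0.0 if criterion == "info_gain" else parent_gini
            continue
        cum_pos = np.cumsum(ys)
        nl = cut + 1.0
        pl = cum_pos[cut].astype(float)
        nr = n - nl
        pr = n_pos - pl
        if criterion == "info_gain":
            child = (nl / n) * _entropy2(pl, nl - pl) + (nr / n) * _entropy2(pr, nr - pr)
            out[j] = parent_ent - child.min()
        else:
            split = (nl / n) * _gini2(pl, nl - pl) + (nr / n) * _gini2(pr, nr - pr)
            out[j] = split.min()
    return out


def _r_value_scores(tbl: FeatureTable, k: int, theta: float) -> np.ndarray:
    """Per-feature class-overlap fraction from 1-D k-nearest neighborhoods."""
    X, y = tbl.X, tbl.y
    n, p = X.shape
    if not 1 <= k < n:
        raise ValueError("k_neighbors must satisfy 1 <= k < n")
    opposite = y[:, None] != y[None, :]
    out = np.empty(p)
    for j in range(p):
        D = np.abs(X[:, j][:, None] - X[:, j][None, :])
        np.fill_diagonal(D, np.inf)
        nbrs = _stable_neighbor_order(D)[:, :k]
        counts = opposite[np.arange(n)[:, None], nbrs].sum(axis=1)
        out[j] = np.mean(counts > theta)
    return out


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

from sklearn.base import BaseEstimator  # noqa: E402


class FilterRanker(BaseEstimator):
    """Score and rank features with one of the eight filter methods.

    Parameters
    ----------
    method : str
        One of :data:`FILTER_METHODS`.
    k_neighbors : int or None
        Neighborhood size for ``relieff`` (default 10, clipped to
        ``min(n1, n2) - 1``) and ``r_value`` (default 5).
    theta : float or None
        Opposite-class count threshold for ``r_value``; defaults to ``k/2``.
    n_iter : int or None
        Number of Relief update iterations; ``None`` uses every sample once
        in index order (deterministic without randomness).
    random_state : int or None
        Only consumed when ``n_iter`` subsamples the data.

    Attributes
    ----------
    scores_ : ndarray of shape (p,)
    orientation_ : str
    ranking_ : RankList
    """

    def __init__(self, method="fisher", k_neighbors=None, theta=None,
                 n_iter=None, random_state=None):
        self.method = method
        self.k_neighbors = k_neighbors
        self.theta = theta
        self.n_iter = n_iter
        self.random_state = random_state

    def _as_table(self, X, y):
        if isinstance(X, FeatureTable):
            return X
        return FeatureTable(np.asarray(X, dtype=float), np.asarray(y))

    def fit(self, X, y=None):
        tbl = self._as_table(X, y)
        method = self.method
        if method not in FILTER_METHODS:
            raise ValueError(f"unknown filter method {method!r}")
        if method == "t_test":
            scores, orient = _t_test_scores(tbl), "larger_better"
        elif method == "fisher":
            scores, orient = _fisher_scores(tbl), "larger_better"
        elif method == "hellinger":
            scores, orient = _hellinger_scores(tbl), "larger_better"
        elif method == "relief":
            scores = _relief_family_scores(tbl, k=1, n_iter=self.n_iter,
                                           rng_seed=self.random_state)
            orient = "larger_better"
        elif method == "relieff":
            k = 10 if self.k_neighbors is None else int(self.k_neighbors)
            if k < 1:
                raise ValueError("k_neighbors must be >= 1")
            k = min(k, min(tbl.n1, tbl.n2) - 1)
            scores = _relief_family_scores(tbl, k=k, n_iter=self.n_iter,
                                           rng_seed=self.random_state)
            orient = "larger_better"
        elif method == "info_gain":
            scores, orient = _best_split_scores(tbl, "info_gain"), "larger_better"
        elif method == "gini":
            scores, orient = _best_split_scores(tbl, "gini"), "smaller_better"
        else:  # r_value
            k = 5 if self.k_neighbors is None else int(self.k_neighbors)
            if k < 1:
                raise ValueError("k_neighbors must be >= 1")
            theta = k / 2.0 if self.theta is None else float(self.theta)
            scores, orient = _r_value_scores(tbl, k, theta), "smaller_better"
        self.scores_ = np.asarray(scores, dtype=float)
        self.orientation_ = orient
        self.ranking_ = rank_from_scores(
            ScoreVector(self.scores_, orient, method)
        )
        return self

    def score_vector_(self) -> ScoreVector:
        return ScoreVector(self.scores_, self.orientation_, self.method)


# ---------------------------------------------------------------------------
# functional surface (thin wrappers over FilterRanker)
# ---------------------------------------------------------------------------

def _score(tbl: FeatureTable, method: str, **kw) -> ScoreVector:
    est = FilterRanker(method=method, **kw).fit(tbl)
    return est.score_vector_()


def score_t_test(tbl: FeatureTable) -> ScoreVector:
    """Absolute Welch t statistic per feature (larger = more important)."""
    return _score(tbl, "t_test")


def score_fisher(tbl: FeatureTable) -> ScoreVector:
    """Fisher score |x̄1 − x̄2| / sqrt(s1² + s2²) per feature."""
    return _score(tbl, "fisher")


def score_hellinger(tbl: FeatureTable) -> ScoreVector:
    """Squared Hellinger distance in [0, 2] between per-class Gaussians."""
    return _score(tbl, "hellinger")


def score_relief(tbl: FeatureTable, n_iter=None, rng_seed=None) -> ScoreVector:
    """Relief weights from single nearest hit/miss updates."""
    return _score(tbl, "relief", n_iter=n_iter, random_state=rng_seed)


def score_relieff(tbl: FeatureTable, k_neighbors=10, n_iter=None,
                  rng_seed=None) -> ScoreVector:
    """ReliefF weights averaging over the k nearest hits and misses."""
    return _score(tbl, "relieff", k_neighbors=k_neighbors, n_iter=n_iter,
                  random_state=rng_seed)


def score_info_gain(tbl: FeatureTable) -> ScoreVector:
    """Information gain (bits) of the best binary threshold per feature."""
    return _score(tbl, "info_gain")


def score_gini(tbl: FeatureTable) -> ScoreVector:
    """Minimal post-split Gini index per feature (smaller = better)."""
    return _score(tbl, "gini")


def score_r_value(tbl: FeatureTable, k_neighbors=5, theta=None) -> ScoreVector:
    """Class-overlap R-value per feature (smaller = better)."""
    return _score(tbl, "r_value", k_neighbors=k_neighbors, theta=theta)


def rank_from_scores(sv: ScoreVector) -> RankList:
    """Deterministic ranking: sort per orientation, ties by ascending index."""
    key = -sv.scores if sv.orientation == "larger_better" else sv.scores
    order = np.lexsort((np.arange(sv.scores.shape[0]), key))
    return RankList(order=order, source=sv.method_name)


def rank_all_filters(tbl: FeatureTable, relieff_k=10, r_value_k=5,
                     theta=None, relief_n_iter=None, rng_seed=None):
    """All eight filter rankings in the fixed :data:`FILTER_METHODS` order."""
    out = []
    for method in FILTER_METHODS:
        kw = {}
        if method == "relieff":
            kw = dict(k_neighbors=relieff_k, n_iter=relief_n_iter,
                      random_state=rng_seed)
        elif method == "relief":
            kw = dict(n_iter=relief_n_iter, random_state=rng_seed)
        elif method == "r_value":
            kw = dict(k_neighbors=r_value_k, theta=theta)
        try:
            est = FilterRanker(method=method, **kw).fit(tbl)
        except Exception as exc:  # annotate which scorer failed
            raise RuntimeError(f"filter {method!r} failed: {exc}") from exc
        out.append(est.ranking_)
    return out
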