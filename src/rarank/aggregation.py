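"""Consensus rankings by weighted Spearman-footrule minimization.

Given m strict rankings f1..fm of the same p features, the consensus δ*
minimizes the weighted total footrule distance

    δ* = argmin_δ Σ_i w_i · d(δ, f_i),   d(a, b) = Σ_t |rank_a(t) − rank_b(t)|

The package's optimizer of record is a Monte Carlo cross-entropy (CE)
search over permutations (:func:`aggregate_ce`): candidate rankings are
sampled position-by-position from an item-by-position probability matrix,
the elite fraction re-estimates the matrix, and exponential smoothing keeps
the search from collapsing early. Two reference solvers are provided: a
p!-enumeration (:func:`aggregate_brute_force`, p ≤ 8) and an exact solver
via linear assignment (:func:`aggregate_exact`) which works because the
unweighted footrule objective separates into per-(item, position) costs.

Concordance between rankings is measured with Kendall's τ
(:func:`kendall_tau`), +1 for identical and −1 for reversed lists.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import kendalltau as _scipy_kendalltau
from sklearn.base import BaseEstimator

from .filters import RankList

__all__ = [
    "CEConfig",
    "AggregationResult",
    "kendall_tau",
    "mean_pairwise_tau",
    "footrule_distance",
    "aggregate_brute_force",
    "aggregate_exact",
    "aggregate_ce",
    "CrossEntropyRankAggregator",
]


@dataclass(frozen=True)
class CEConfig:
    """Hyperparameters of the cross-entropy permutation search.

    ``samples_per_iter=None`` resolves to ``max(10, 10·p²)`` at fit time.
    """

    samples_per_iter: int | None = None
    elite_quantile: float = 0.1
    smoothing: float = 0.7
    max_iters: int = 100
    convergence_window: int = 5
    rng_seed: int | None = None

    def __post_init__(self):
        if self.samples_per_iter is not None and self.samples_per_iter < 10:
            raise ValueError("samples_per_iter must be >= 10")
        if not 0 < self.elite_quantile < 1:
            raise ValueError("elite_quantile must be in (0, 1)")
        if not 0 < self.smoothing <= 1:
            raise ValueError("smoothing must be in (0, 1]")


@dataclass(frozen=True)
class AggregationResult:
    optimal_list: RankList
    objective: float
    trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    seed: int | None = None


def _as_ranks(lst) -> np.ndarray:
    """Rank vector (1 = best) from a RankList or an array of ranks."""
    if isinstance(lst, RankList):
        return lst.ranks
    r = np.asarray(lst, dtype=np.int64)
    if sorted(r.tolist()) != list(range(1, r.shape[0] + 1)):
        raise ValueError("expected a strict rank vector 1..p")
    return r


def kendall_tau(f1, f2) -> float:
    """Kendall's τ between two strict rankings of the same feature set."""
    r1, r2 = _as_ranks(f1), _as_ranks(f2)
    if r1.shape != r2.shape:
        raise ValueError("rankings cover different feature sets")
    return float(_scipy_kendalltau(r1, r2).statistic)


def mean_pairwise_tau(lists) -> float:
    """Mean Kendall's τ over all unordered pairs of m ≥ 2 rankings."""
    ranks = [_as_ranks(l) for l in lists]
    if len(ranks) < 2:
        raise ValueError("need at least two rankings")
    taus = [kendall_tau(a, b) for a, b in itertools.combinations(ranks, 2)]
    return float(np.mean(taus))


def footrule_distance(a, b, rank_scores=None) -> float:
    """Spearman footrule distance Σ_t |rank_a(t) − rank_b(t)|.

    ``rank_scores``, if given, is a length-p vector M mapping rank positions
    to scores; each term is then weighted by |M[rank_a(t)] − M[rank_b(t)]|
    (the score-weighted variant). The default is the unweighted form.
    """
    ra, rb = _as_ranks(a), _as_ranks(b)
    if ra.shape != rb.shape:
        raise ValueError("rankings cover different feature sets")
    diff = np.abs(ra - rb)
    if rank_scores is None:
        return float(diff.sum())
    M = np.asarray(rank_scores, dtype=float)
    if M.shape != ra.shape:
        raise ValueError("rank_scores must have length p")
    return float((np.abs(M[ra - 1] - M[rb - 1]) * diff).sum())


def _prepare_problem(lists, weights):
    pos = np.stack([_as_ranks(l) for l in lists]).astype(float)  # (m, p)
    m, p = pos.shape
    if m < 2:
        raise ValueError("need at least two rankings to aggregate")
    if weights is None:
        w = np.full(m, 1.0 / m)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (m,) or np.any(w < 0):
            raise ValueError("weights must be m nonnegative reals")
        w = w / w.sum()
    return pos, w, m, p


def _objective_many(inv_pos, pos, w):
    """Objectives of candidate rankings.

    ``inv_pos``: (N, p) array, rank (1-based) of each item under each
    candidate; ``pos``: (m, p) ranks under the input lists; ``w``: weights.
    """
    # (N, m, p) broadcast is fine at the problem sizes used here
    return np.einsum(
        "i,nip->n", w, np.abs(inv_pos[:, None, :] - pos[None, :, :])
    )


def _cost_matrix(pos, w):
    """cost[j, t] = Σ_i w_i |(t+1) − rank_i(j)|; footrule separates per item."""
    p = pos.shape[1]
    positions = np.arange(1, p + 1)
    return np.einsum("i,ijt->jt", w, np.abs(positions[None, None, :] - pos[:, :, None]))


def aggregate_exact(lists, weights=None) -> AggregationResult:
    """Exact footrule consensus via the linear assignment problem."""
    pos, w, m, p = _prepare_problem(lists, weights)
    cost = _cost_matrix(pos, w)
    items, slots = linear_sum_assignment(cost)
    order = np.empty(p, dtype=np.int64)
    order[slots] = items
    obj = float(cost[items, slots].sum())
    return AggregationResult(RankList(order, source="exact"), obj)


def aggregate_brute_force(lists, weights=None) -> AggregationResult:
    """Global footrule consensus by enumerating all p! permutations (p ≤ 8).

    Ties between equally optimal permutations are broken lexicographically
    (the enumeration visits orders in lexicographic sequence and keeps the
    first strict improvement).
    """
    pos, w, m, p = _prepare_problem(lists, weights)
    if p > 8:
        raise ValueError("brute force is limited to p <= 8; use aggregate_ce")
    cost = _cost_matrix(pos, w)
    best_obj, best_order = np.inf, None
    for perm in itertools.permutations(range(p)):
        obj = cost[list(perm), range(p)].sum()
        if obj < best_obj:
            best_obj, best_order = obj, perm
    return AggregationResult(
        RankList(np.array(best_order), source="brute_force"), float(best_obj)
    )


class CrossEntropyRankAggregator(BaseEstimator):
    """Cross-entropy Monte Carlo search for the footrule consensus ranking.

    The search state is a p×p item-by-position probability matrix
    initialized uniformly at 1/p. Each iteration draws
    ``samples_per_iter`` permutations position by position (renormalizing
    over the still-unplaced items), scores them with the weighted footrule
    objective, and re-fits the matrix to the elite ``elite_quantile``
    fraction with exponential smoothing. The best permutation ever seen is
    returned; the search stops once it has not improved for
    ``convergence_window`` consecutive iterations.

    Attributes
    ----------
    consensus_ : RankList
    objective_ : float
    trace_ : ndarray — best-ever objective per iteration (non-increasing).
    """

    def __init__(self, samples_per_iter=None, elite_quantile=0.1,
                 smoothing=0.7, max_iters=100, convergence_window=5,
                 random_state=None):
        self.samples_per_iter = samples_per_iter
        self.elite_quantile = elite_quantile
        self.smoothing = smoothing
        self.max_iters = max_iters
        self.convergence_window = convergence_window
        self.random_state = random_state

    def fit(self, lists, weights=None):
        cfg = CEConfig(self.samples_per_iter, self.elite_quantile,
                       self.smoothing, self.max_iters,
                       self.convergence_window, self.random_state)
        pos, w, m, p = _prepare_problem(lists, weights)
        N = cfg.samples_per_iter or max(10, 10 * p * p)
        n_elite = max(1, int(np.ceil(cfg.elite_quantile * N)))
        rng = np.random.default_rng(cfg.rng_seed)

        M = np.full((p, p), 1.0 / p)
        best_obj, best_order = np.inf, None
        trace, stall = [], 0
        for _ in range(cfg.max_iters):
            perms = self._sample(M, N, rng)                      # (N, p) item ids
            inv = np.empty_like(perms)
            inv[np.arange(N)[:, None], perms] = np.arange(1, p + 1)[None, :]
            objs = _objective_many(inv.astype(float), pos, w)
            elite_idx = np.argsort(objs, kind="stable")[:n_elite]

            improved = False
            i_best = elite_idx[0]
            if objs[i_best] < best_obj or (
                objs[i_best] == best_obj
                and best_order is not None
                and perms[i_best].tolist() < best_order.tolist()
            ):
                improved = objs[i_best] < best_obj
                best_obj = float(objs[i_best])
                best_order = perms[i_best].copy()
            trace.append(best_obj)
            stall = 0 if improved else stall + 1
            if stall >= cfg.convergence_window:
                break

            freq = np.zeros((p, p))
            np.add.at(freq, (perms[elite_idx].ravel(),
                             np.tile(np.arange(p), n_elite)), 1.0)
            M = cfg.smoothing * (freq / n_elite) + (1 - cfg.smoothing) * M

        self.consensus_ = RankList(best_order, source="ce")
        self.objective_ = best_obj
        self.trace_ = np.asarray(trace)
        self.n_iter_ = len(trace)
        return self

    @staticmethod
    def _sample(M, N, rng):
        p = M.shape[0]
        if np.any(M.sum(axis=0) <= 0):
            raise RuntimeError("degenerate all-zero column in the CE matrix")
        perms = np.empty((N, p), dtype=np.int64)
        avail = np.ones((N, p), dtype=bool)
        u = rng.random((N, p))
        rows = np.arange(N)
        for t in range(p):
            probs = M[:, t][None, :] * avail
            tot = probs.sum(axis=1, keepdims=True)
            # rows whose remaining items all have zero mass: renormalize uniform
            dead = tot[:, 0] <= 0
            if np.any(dead):
                probs[dead] = avail[dead]
                tot = probs.sum(axis=1, keepdims=True)
            cdf = np.cumsum(probs, axis=1)
            choice = (cdf < u[:, t][:, None] * tot).sum(axis=1)
            perms[:, t] = choice
            avail[rows, choice] = False
        return perms


def aggregate_ce(lists, weights=None, config: CEConfig | None = None) -> AggregationResult:
    """Footrule consensus by cross-entropy Monte Carlo search."""
    cfg = config or CEConfig()
    est = CrossEntropyRankAggregator(
        samples_per_iter=cfg.samples_per_iter,
        elite_quantile=cfg.elite_quantile,
        smoothing=cfg.smoothing,
        max_iters=cfg.max_iters,
        convergence_window=cfg.convergence_window,
        random_state=cfg.rng_seed,
    ).fit(lists, weights)
    return AggregationResult(est.consensus_, est.objective_, est.trace_,
                             seed=cfg.rng_seed)
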