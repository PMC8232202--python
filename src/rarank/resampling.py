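"""Class re-balancing by random sampling, SMOTE and the smoothed bootstrap.

Seven re-balance regimes ("cases") are supported; each produces a table
whose class sizes follow the case's balance rule exactly:

1. no re-sampling (identity);
2. hybrid A — SMOTE doubles the minority to 2·n1 and the majority is
   randomly cut to the same size;
3. hybrid B — the whole dataset is replaced by n smoothed-bootstrap draws
   with (approximately) equal class sizes;
4. over-sampling A — minority rows randomly duplicated up to n2;
5. over-sampling B — smoothed-bootstrap synthetic minority rows added up
   to n2;
6. under-sampling A — majority randomly cut to n1;
7. under-sampling B — the majority is replaced by n1 smoothed-bootstrap
   draws from the majority.

All samplers expose an imbalanced-learn-style ``fit_resample(X, y)`` and
are bit-reproducible from their ``random_state``. The smoothed bootstrap
draws a source row uniformly within its class and perturbs it with a
diagonal Gaussian kernel whose per-feature bandwidth follows Silverman's
rule, 0.9 · min(sd, IQR/1.34) · nk^(−1/5), computed per class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .table import FeatureTable

__all__ = [
    "ResamplePlan",
    "ResampleResult",
    "RandomOverSampler",
    "RandomUnderSampler",
    "SMOTEOverSampler",
    "SmoothedBootstrapSampler",
    "CaseResampler",
    "random_oversample",
    "random_undersample",
    "smote_generate",
    "smoothed_bootstrap",
    "apply_case",
    "CASE_NAMES",
]

CASE_NAMES = {
    1: "no re-sampling (RA)",
    2: "hybrid A: SMOTE minority + random under-sampling",
    3: "hybrid B: full smoothed-bootstrap re-draw",
    4: "over-sampling A: random minority duplication",
    5: "over-sampling B: smoothed-bootstrap minority",
    6: "under-sampling A: random majority removal",
    7: "under-sampling B: smoothed-bootstrap majority",
}


@dataclass(frozen=True)
class ResamplePlan:
    case_id: int = 1
    rng_seed: int | None = None
    smote_k: int = 5
    bandwidth_rule: str = "silverman"

    def __post_init__(self):
        if self.case_id not in CASE_NAMES:
            raise ValueError(f"unknown case id {self.case_id}")


@dataclass(frozen=True)
class ResampleResult:
    table: FeatureTable
    counts_before: tuple
    counts_after: tuple
    synthetic: np.ndarray  # bool mask over output rows; True = synthetic

    def __post_init__(self):
        object.__setattr__(self, "synthetic",
                           np.asarray(self.synthetic, dtype=bool))


# ---------------------------------------------------------------------------
# primitive generators
# ---------------------------------------------------------------------------

def smote_generate(minority_X, n_new: int, k: int = 5, rng=None) -> np.ndarray:
    """SMOTE interpolation: x' = x_i + u·(x_ih − x_i), u ~ Uniform(0, 1).

    ``x_i`` is a uniformly chosen minority seed, ``x_ih`` one of its k
    nearest minority neighbors (Euclidean; ties by ascending index), and a
    single scalar u is drawn per synthetic point.
    """
    X = np.asarray(minority_X, dtype=float)
    if n_new < 0:
        raise ValueError("n_new must be >= 0")
    if X.shape[0] < 2:
        raise ValueError("SMOTE needs at least 2 minority samples")
    if n_new == 0:
        return np.empty((0, X.shape[1]))
    rng = np.random.default_rng(rng)
    k = min(int(k), X.shape[0] - 1)
    if k < 1:
        raise ValueError("k must be >= 1")
    sq = np.sum(X**2, axis=1)
    D = sq[:, None] + sq[None, :] - 2.0 * X @ X.T
    np.fill_diagonal(D, np.inf)
    nbrs = np.argsort(D, axis=1, kind="stable")[:, :k]
    seeds = rng.integers(0, X.shape[0], size=n_new)
    picks = nbrs[seeds, rng.integers(0, k, size=n_new)]
    u = rng.random(n_new)[:, None]
    return X[seeds] + u * (X[picks] - X[seeds])


def _silverman_bandwidth(Xc: np.ndarray, X_all: np.ndarray) -> np.ndarray:
    nk = Xc.shape[0]
    sd = Xc.std(axis=0, ddof=1) if nk > 1 else np.zeros(Xc.shape[1])
    q75, q25 = np.percentile(Xc, [75, 25], axis=0)
    spread = np.minimum(sd, (q75 - q25) / 1.34)
    h = 0.9 * spread * nk ** (-0.2)
    if np.any(h <= 0):
        # degenerate class spread: fall back to a small fraction of the
        # overall per-feature scale so draws stay near the source rows
        scale = X_all.max(axis=0) - X_all.min(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        warnings.warn("degenerate class spread; using fallback bandwidth")
        h = np.where(h > 0, h, 0.01 * scale)
    return h


def smoothed_bootstrap(tbl: FeatureTable, n_new_per_class,
                       bandwidth_rule: str = "silverman", rng=None):
    """Kernel-perturbed bootstrap draws per class.

    Returns ``(X_new, y_new)`` with exactly ``n_new_per_class = (m1, m2)``
    synthetic minority (y=1) and majority (y=0) rows.
    """
    if bandwidth_rule != "silverman":
        raise ValueError(f"unknown bandwidth rule {bandwidth_rule!r}")
    m1, m2 = (int(v) for v in n_new_per_class)
    if m1 < 0 or m2 < 0:
        raise ValueError("requested counts must be >= 0")
    rng = np.random.default_rng(rng)
    rows_X, rows_y = [], []
    for label, m in ((1, m1), (0, m2)):
        if m == 0:
            continue
        Xc = tbl.X[tbl.y == label]
        if Xc.shape[0] == 0:
            raise ValueError("cannot bootstrap from an empty class")
        h = _silverman_bandwidth(Xc, tbl.X)
        src = rng.integers(0, Xc.shape[0], size=m)
        noise = rng.standard_normal((m, tbl.p)) * h[None, :]
        rows_X.append(Xc[src] + noise)
        rows_y.append(np.full(m, label, dtype=np.int64))
    if not rows_X:
        return np.empty((0, tbl.p)), np.empty(0, dtype=np.int64)
    return np.vstack(rows_X), np.concatenate(rows_y)


# ---------------------------------------------------------------------------
# samplers (estimator surface)
# ---------------------------------------------------------------------------

class _BaseSampler(BaseEstimator):
    def __init__(self, random_state=None):
        self.random_state = random_state

    def _split(self, tbl: FeatureTable):
        return tbl.X[tbl.y == 1], tbl.X[tbl.y == 0]

    def fit_resample(self, X, y=None) -> ResampleResult:
        tbl = X if isinstance(X, FeatureTable) else FeatureTable(
            np.asarray(X, dtype=float), np.asarray(y))
        return self._resample(tbl, np.random.default_rng(self.random_state))


def _assemble(tbl, X1, X2, syn1, syn2):
    """Stack minority block then majority block into a ResampleResult."""
    X = np.vstack([X1, X2])
    y = np.concatenate([np.ones(len(X1), dtype=np.int64),
                        np.zeros(len(X2), dtype=np.int64)])
    syn = np.concatenate([syn1, syn2])
    out = FeatureTable(X, y, tbl.feature_names)
    return ResampleResult(out, (tbl.n1, tbl.n2), (out.n1, out.n2), syn)


class RandomOverSampler(_BaseSampler):
    """Grow the minority to ``target_n1`` by duplication with replacement."""

    def __init__(self, target_n1=None, random_state=None):
        super().__init__(random_state)
        self.target_n1 = target_n1

    def _resample(self, tbl, rng):
        X1, X2 = self._split(tbl)
        target = tbl.n2 if self.target_n1 is None else int(self.target_n1)
        if target < tbl.n1:
            raise ValueError("target_n1 must be >= current minority size")
        extra = rng.integers(0, tbl.n1, size=target - tbl.n1)
        X1_new = np.vstack([X1, X1[extra]])
        syn1 = np.concatenate([np.zeros(tbl.n1, bool), np.ones(len(extra), bool)])
        return _assemble(tbl, X1_new, X2, syn1, np.zeros(tbl.n2, bool))


class RandomUnderSampler(_BaseSampler):
    """Cut the majority to ``target_n2`` by sampling without replacement."""

    def __init__(self, target_n2=None, random_state=None):
        super().__init__(random_state)
        self.target_n2 = target_n2

    def _resample(self, tbl, rng):
        X1, X2 = self._split(tbl)
        target = tbl.n1 if self.target_n2 is None else int(self.target_n2)
        if target > tbl.n2:
            raise ValueError("target_n2 must be <= current majority size")
        keep = np.sort(rng.choice(tbl.n2, size=target, replace=False))
        return _assemble(tbl, X1, X2[keep],
                         np.zeros(tbl.n1, bool), np.zeros(target, bool))


class SMOTEOverSampler(_BaseSampler):
    """Add SMOTE-interpolated minority rows up to ``target_n1``."""

    def __init__(self, target_n1=None, k_neighbors=5, random_state=None):
        super().__init__(random_state)
        self.target_n1 = target_n1
        self.k_neighbors = k_neighbors

    def _resample(self, tbl, rng):
        X1, X2 = self._split(tbl)
        target = tbl.n2 if self.target_n1 is None else int(self.target_n1)
        if target < tbl.n1:
            raise ValueError("target_n1 must be >= current minority size")
        new = smote_generate(X1, target - tbl.n1, self.k_neighbors, rng)
        X1_new = np.vstack([X1, new])
        syn1 = np.concatenate([np.zeros(tbl.n1, bool), np.ones(len(new), bool)])
        return _assemble(tbl, X1_new, X2, syn1, np.zeros(tbl.n2, bool))


class SmoothedBootstrapSampler(_BaseSampler):
    """Replace or augment classes with kernel-bootstrap draws.

    ``mode``:
      * ``"augment_minority"`` — add synthetic minority rows up to
        ``target`` (default n2);
      * ``"replace_majority"`` — replace the majority by ``target``
        (default n1) synthetic majority rows;
      * ``"full"`` — replace the whole table by synthetic rows with class
        sizes ``(⌊n/2⌋ minority, ⌈n/2⌉ majority)``.
    """

    def __init__(self, mode="augment_minority", target=None,
                 bandwidth_rule="silverman", random_state=None):
        super().__init__(random_state)
        self.mode = mode
        self.target = target
        self.bandwidth_rule = bandwidth_rule

    def _resample(self, tbl, rng):
        X1, X2 = self._split(tbl)
        if self.mode == "augment_minority":
            target = tbl.n2 if self.target is None else int(self.target)
            if target < tbl.n1:
                raise ValueError("target must be >= current minority size")
            Xn, _ = smoothed_bootstrap(tbl, (target - tbl.n1, 0),
                                       self.bandwidth_rule, rng)
            X1_new = np.vstack([X1, Xn])
            syn1 = np.concatenate([np.zeros(tbl.n1, bool), np.ones(len(Xn), bool)])
            return _assemble(tbl, X1_new, X2, syn1, np.zeros(tbl.n2, bool))
        if self.mode == "replace_majority":
            target = tbl.n1 if self.target is None else int(self.target)
            Xn, _ = smoothed_bootstrap(tbl, (0, target), self.bandwidth_rule, rng)
            return _assemble(tbl, X1, Xn,
                             np.zeros(tbl.n1, bool), np.ones(len(Xn), bool))
        if self.mode == "full":
            n = tbl.n if self.target is None else int(self.target)
            m1, m2 = n // 2, n - n // 2  # minority gets the floor on odd n
            Xn, yn = smoothed_bootstrap(tbl, (m1, m2), self.bandwidth_rule, rng)
            out = FeatureTable(Xn, yn, tbl.feature_names)
            return ResampleResult(out, (tbl.n1, tbl.n2), (out.n1, out.n2),
                                  np.ones(out.n, bool))
        raise ValueError(f"unknown mode {self.mode!r}")


class CaseResampler(_BaseSampler):
    """Apply one of the seven re-balance cases (see module docstring)."""

    def __init__(self, case_id=1, smote_k=5, bandwidth_rule="silverman",
                 random_state=None):
        super().__init__(random_state)
        self.case_id = case_id
        self.smote_k = smote_k
        self.bandwidth_rule = bandwidth_rule

    def _resample(self, tbl, rng):
        case = int(self.case_id)
        if case not in CASE_NAMES:
            raise ValueError(f"unknown case id {case}")
        if case == 1:
            return ResampleResult(tbl, (tbl.n1, tbl.n2), (tbl.n1, tbl.n2),
                                  np.zeros(tbl.n, bool))
        if case == 2:
            # both classes meet at 2·n1, clamped to n2 when the majority is
            # smaller than twice the minority (mild imbalance)
            target = min(2 * tbl.n1, tbl.n2)
            mid = SMOTEOverSampler(target, self.smote_k)._resample(tbl, rng)
            res = RandomUnderSampler(target)._resample(mid.table, rng)
            # majority rows are all original; minority synthetic flags carry over
            syn = np.concatenate([mid.synthetic[:target],
                                  np.zeros(res.table.n2, bool)])
            return ResampleResult(res.table, (tbl.n1, tbl.n2),
                                  (res.table.n1, res.table.n2), syn)
        if case == 3:
            return SmoothedBootstrapSampler("full", bandwidth_rule=self.bandwidth_rule).\
                _resample(tbl, rng)
        if case == 4:
            return RandomOverSampler(tbl.n2)._resample(tbl, rng)
        if case == 5:
            return SmoothedBootstrapSampler(
                "augment_minority", tbl.n2, self.bandwidth_rule)._resample(tbl, rng)
        if case == 6:
            return RandomUnderSampler(tbl.n1)._resample(tbl, rng)
        # case 7
        return SmoothedBootstrapSampler(
            "replace_majority", tbl.n1, self.bandwidth_rule)._resample(tbl, rng)


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def random_oversample(tbl: FeatureTable, target_n1: int, rng=None) -> ResampleResult:
    return RandomOverSampler(target_n1, random_state=rng).fit_resample(tbl)


def random_undersample(tbl: FeatureTable, target_n2: int, rng=None) -> ResampleResult:
    return RandomUnderSampler(target_n2, random_state=rng).fit_resample(tbl)


def apply_case(tbl: FeatureTable, plan: ResamplePlan) -> ResampleResult:
    return CaseResampler(plan.case_id, plan.smote_k, plan.bandwidth_rule,
                         random_state=plan.rng_seed).fit_resample(tbl)
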