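"""Two-class Gaussian simulations and the ranking-concordance study.

The generator emulates a metabolomics-style screening problem: both
classes are multivariate normal with a shared covariance (identity by
default) and differ only by a mean shift on the informative features. The
default study conditions are 960 samples split by a majority:minority
ratio from {1, 3, 9, 31, 95}, and two canonical scenarios:

* case one — p = 8, every feature informative, mean shifts
  (2.4, 2.2, 2.0, 1.8, 1.6, 1.4, 1.2, 1.0);
* case two — p = 16, the same eight informative features plus eight
  irrelevant (zero-shift) features.

:func:`concordance_study` measures, per imbalance ratio, how much the
eight filter rankings agree with each other (mean pairwise Kendall τ over
all 28 pairs), averaged over independent repeats. Agreement is highest at
balance and decays as the imbalance ratio grows — the motivating
observation for aggregating rankings after re-balancing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aggregation import mean_pairwise_tau
from .filters import rank_all_filters
from .table import FeatureTable

__all__ = [
    "SimulationConfig",
    "CASE_ONE_SHIFTS",
    "STUDY_RATIOS",
    "case_one_config",
    "case_two_config",
    "generate_two_class_gaussian",
    "concordance_study",
]

#: Mean shifts of the informative features in the canonical scenarios.
CASE_ONE_SHIFTS = (2.4, 2.2, 2.0, 1.8, 1.6, 1.4, 1.2, 1.0)

#: Majority:minority ratios of the concordance study.
STUDY_RATIOS = (1, 3, 9, 31, 95)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the two-class Gaussian generator."""

    mean_shift: tuple
    covariance: np.ndarray | None = None  # None -> identity
    n_total: int = 960
    ratio: float = 1
    repeats: int = 100
    rng_seed: int | None = None

    def __post_init__(self):
        shift = tuple(float(v) for v in self.mean_shift)
        object.__setattr__(self, "mean_shift", shift)
        if len(shift) < 2:
            raise ValueError("need at least 2 features")
        if self.covariance is not None:
            S = np.asarray(self.covariance, dtype=float)
            if S.shape != (len(shift), len(shift)):
                raise ValueError("covariance shape does not match p")
            if not np.allclose(S, S.T):
                raise ValueError("covariance must be symmetric")
            if np.any(np.linalg.eigvalsh(S) <= 0):
                raise ValueError("covariance must be positive definite")
            object.__setattr__(self, "covariance", S)
        n1, n2 = self.class_sizes
        if n1 < 2:
            raise ValueError("minority class would have fewer than 2 samples")

    @property
    def p(self) -> int:
        return len(self.mean_shift)

    @property
    def class_sizes(self):
        """(minority, majority) sizes; the split must be exact."""
        r = self.ratio
        n1 = self.n_total / (r + 1)
        if abs(n1 - round(n1)) > 1e-9:
            raise ValueError(
                f"n_total={self.n_total} does not split evenly at ratio {r}:1"
            )
        n1 = int(round(n1))
        return n1, self.n_total - n1


def case_one_config(ratio=1, n_total=960, repeats=100, rng_seed=None) -> SimulationConfig:
    """Eight informative features, shifts 2.4 down to 1.0."""
    return SimulationConfig(CASE_ONE_SHIFTS, None, n_total, ratio, repeats, rng_seed)


def case_two_config(ratio=1, n_total=960, repeats=100, rng_seed=None) -> SimulationConfig:
    """Case one plus eight irrelevant (zero-shift) features."""
    return SimulationConfig(CASE_ONE_SHIFTS + (0.0,) * 8, None, n_total,
                            ratio, repeats, rng_seed)


def generate_two_class_gaussian(cfg: SimulationConfig, rng=None) -> FeatureTable:
    """Draw one table: majority ~ N(0, Σ), minority ~ N(shift, Σ)."""
    rng = np.random.default_rng(cfg.rng_seed if rng is None else rng)
    n1, n2 = cfg.class_sizes
    p = cfg.p
    shift = np.asarray(cfg.mean_shift)
    if cfg.covariance is None:
        X2 = rng.standard_normal((n2, p))
        X1 = rng.standard_normal((n1, p)) + shift
    else:
        L = np.linalg.cholesky(cfg.covariance)
        X2 = rng.standard_normal((n2, p)) @ L.T
        X1 = rng.standard_normal((n1, p)) @ L.T + shift
    X = np.vstack([X1, X2])
    y = np.concatenate([np.ones(n1, dtype=np.int64), np.zeros(n2, dtype=np.int64)])
    return FeatureTable(X, y)


def concordance_study(cfg: SimulationConfig, ratios=STUDY_RATIOS,
                      repeats=None, rng_seed=None, relieff_k=10,
                      r_value_k=5) -> pd.DataFrame:
    """Mean pairwise Kendall τ of the eight filter rankings per ratio.

    Each (ratio, repeat) cell uses an independently spawned RNG stream so
    the study is reproducible and repeats are independent. Returns a
    DataFrame with columns ``ratio, mean_tau, sd_tau, repeats``.
    """
    repeats = cfg.repeats if repeats is None else int(repeats)
    seed = cfg.rng_seed if rng_seed is None else rng_seed
    root = np.random.SeedSequence(seed)
    rows = []
    for ratio in ratios:
        rcfg = SimulationConfig(cfg.mean_shift, cfg.covariance, cfg.n_total,
                                ratio, repeats, None)
        taus = []
        for child in root.spawn(repeats):
            tbl = generate_two_class_gaussian(rcfg, np.random.default_rng(child))
            lists = rank_all_filters(tbl, relieff_k=relieff_k, r_value_k=r_value_k)
            taus.append(mean_pairwise_tau(lists))
        rows.append({"ratio": float(ratio), "mean_tau": float(np.mean(taus)),
                     "sd_tau": float(np.std(taus, ddof=1)) if repeats > 1 else 0.0,
                     "repeats": repeats})
    return pd.DataFrame(rows)
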