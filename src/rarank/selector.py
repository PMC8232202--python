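"""The RAR feature selector: re-balance, rank with eight filters, aggregate.

:class:`RARSelector` is a scikit-learn transformer (``SelectorMixin``): on
``fit`` it optionally re-balances the two-class data (one of the seven
cases), computes the eight filter rankings on the (re-balanced) table,
fuses them into a consensus ranking by cross-entropy footrule
minimization, and — if asked — picks the number of features to keep by
cross-validated AUCPRC. ``transform`` then keeps the selected columns, so
the selector composes with ordinary sklearn pipelines.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from .aggregation import CEConfig, aggregate_ce
from .evaluation import select_top_k_cv
from .filters import rank_all_filters
from .resampling import CaseResampler
from .table import FeatureTable

__all__ = ["RARSelector"]


class RARSelector(SelectorMixin, BaseEstimator):
    """Consensus feature selection for class-imbalanced two-class data.

    Parameters
    ----------
    case : int, default 1
        Re-balance case (1 = none; 2–7 per :mod:`rarank.resampling`).
    n_features_to_select : int, "cv" or None, default None
        ``None`` keeps all features (the selector is then a pure ranker);
        an int keeps the top-k of the consensus ranking; ``"cv"`` picks k
        by stratified cross-validated AUCPRC with a random forest.
    cv : int, default 5
        Folds for the ``"cv"`` search.
    n_estimators : int, default 500
        Trees of the random forest used in the ``"cv"`` search.
    relieff_k, r_value_k : int
        Neighborhood sizes of the ReliefF and R-value filters.
    smote_k : int, default 5
        SMOTE neighborhood for case 2.
    ce_samples, ce_elite, ce_smoothing, ce_max_iters, ce_window
        Cross-entropy search hyperparameters (``ce_samples=None`` resolves
        to 10·p²).
    random_state : int or None
        Seeds re-balancing, the CE search and the CV search.

    Attributes
    ----------
    ranking_ : RankList — the consensus ranking (rank 1 = most important).
    filter_rankings_ : list of RankList — the eight per-filter rankings.
    aggregation_ : AggregationResult
    resample_ : ResampleResult
    k_opt_ : int — number of features kept.
    cv_curve_ : DataFrame or None — mean AUCPRC vs k (only for "cv").
    """

    def __init__(self, case=1, n_features_to_select=None, cv=5,
                 n_estimators=500, relieff_k=10, r_value_k=5, smote_k=5,
                 ce_samples=None, ce_elite=0.1, ce_smoothing=0.7,
                 ce_max_iters=100, ce_window=5, random_state=None):
        self.case = case
        self.n_features_to_select = n_features_to_select
        self.cv = cv
        self.n_estimators = n_estimators
        self.relieff_k = relieff_k
        self.r_value_k = r_value_k
        self.smote_k = smote_k
        self.ce_samples = ce_samples
        self.ce_elite = ce_elite
        self.ce_smoothing = ce_smoothing
        self.ce_max_iters = ce_max_iters
        self.ce_window = ce_window
        self.random_state = random_state

    def fit(self, X, y=None):
        tbl = X if isinstance(X, FeatureTable) else FeatureTable(
            np.asarray(X, dtype=float), np.asarray(y))
        self.n_features_in_ = tbl.p
        self.feature_names_in_ = np.asarray(tbl.feature_names, dtype=object)
        seeds = np.random.SeedSequence(self.random_state).spawn(3)

        self.resample_ = CaseResampler(
            self.case, smote_k=self.smote_k,
            random_state=np.random.default_rng(seeds[0]),
        ).fit_resample(tbl)
        work = self.resample_.table

        self.filter_rankings_ = rank_all_filters(
            work, relieff_k=self.relieff_k, r_value_k=self.r_value_k)
        self.aggregation_ = aggregate_ce(
            self.filter_rankings_,
            config=CEConfig(self.ce_samples, self.ce_elite, self.ce_smoothing,
                            self.ce_max_iters, self.ce_window,
                            int(seeds[1].generate_state(1)[0] % (2**31))))
        self.ranking_ = self.aggregation_.optimal_list

        sel = self.n_features_to_select
        self.cv_curve_ = None
        if sel is None:
            self.k_opt_ = tbl.p
        elif sel == "cv":
            self.k_opt_, self.cv_curve_ = select_top_k_cv(
                work, self.ranking_, folds=self.cv,
                classifier_cfg={"n_estimators": self.n_estimators},
                random_state=int(seeds[2].generate_state(1)[0] % (2**31)))
        else:
            k = int(sel)
            if not 1 <= k <= tbl.p:
                raise ValueError("n_features_to_select out of range")
            self.k_opt_ = k
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "ranking_")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.ranking_.order[: self.k_opt_]] = True
        return mask

    def transform(self, X):
        if isinstance(X, FeatureTable):
            X = X.X
        return np.asarray(X)[:, self._get_support_mask()]
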