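"""Imbalance-aware screening metrics and the top-k feature search.

Hard-label quality is summarized by the geometric mean of sensitivity and
specificity (Gmean) and by F1; ranking quality by the area under the ROC
curve and under the precision-recall curve (the latter estimated as
average precision, the estimator of choice for imbalanced problems).

:func:`select_top_k_cv` searches for the number of top-ranked features to
keep: for every k it evaluates a random-forest classifier on the top-k
features by stratified k-fold cross-validated AUCPRC and returns the
smallest k attaining the maximum together with the whole curve.

:func:`rowmax_proportion` is a small utility for method-comparison tables:
it counts the rows in which a focal column reaches the row maximum of a
set of comparison columns (ties count as reaching it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (auc as _sk_auc, average_precision_score,
                             precision_recall_curve, roc_auc_score)
from sklearn.model_selection import StratifiedKFold

from .filters import RankList
from .table import FeatureTable

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "threshold_metrics",
    "auc_roc",
    "auc_prc",
    "confusion_from_scores",
    "metric_report",
    "select_top_k_cv",
    "rowmax_proportion",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def positives(self) -> int:
        return self.TP + self.FN

    @property
    def negatives(self) -> int:
        return self.TN + self.FP


@dataclass(frozen=True)
class MetricReport:
    gmean: float
    f1: float
    auc_roc: float
    auc_prc: float
    n_features_used: int
    confusion: ConfusionCounts | None = None


def threshold_metrics(cc: ConfusionCounts):
    """(Gmean, F1) from hard-label confusion counts.

    Gmean = sqrt(TPR · TNR); F1 is the harmonic mean of precision and
    recall. Undefined ratios (zero denominators) are reported as 0.
    """
    if cc.positives == 0 or cc.negatives == 0:
        raise ValueError("need at least one positive and one negative")
    tpr = cc.TP / cc.positives
    tnr = cc.TN / cc.negatives
    gmean = float(np.sqrt(tpr * tnr))
    denom = 2 * cc.TP + cc.FP + cc.FN
    if denom == 0:
        warnings.warn("F1 undefined (no predicted or actual positives); using 0")
        f1 = 0.0
    else:
        f1 = 2 * cc.TP / denom
    return gmean, float(f1)


def _check_binary(labels):
    labels = np.asarray(labels)
    if labels.dtype.kind not in "biu":
        labels = labels.astype(int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    return labels


def auc_roc(scores, labels) -> float:
    """Area under the ROC curve (= P(score_pos > score_neg), ties ½)."""
    return float(roc_auc_score(_check_binary(labels), np.asarray(scores, float)))


def auc_prc(scores, labels, estimator: str = "average_precision") -> float:
    """Area under the precision-recall curve.

    ``estimator="average_precision"`` (default) sums precision at each
    positive over recall increments; ``"trapezoid"`` integrates the PR
    curve with the trapezoidal rule.
    """
    labels = _check_binary(labels)
    scores = np.asarray(scores, float)
    if estimator == "average_precision":
        return float(average_precision_score(labels, scores))
    if estimator == "trapezoid":
        prec, rec, _ = precision_recall_curve(labels, scores)
        return float(_sk_auc(rec, prec))
    raise ValueError(f"unknown estimator {estimator!r}")


def confusion_from_scores(scores, labels, threshold: float = 0.5) -> ConfusionCounts:
    """Confusion counts after thresholding probability scores at 0.5."""
    labels = _check_binary(labels)
    pred = np.asarray(scores, float) >= threshold
    pos = labels == 1
    return ConfusionCounts(
        TP=int(np.sum(pred & pos)), FP=int(np.sum(pred & ~pos)),
        TN=int(np.sum(~pred & ~pos)), FN=int(np.sum(~pred & pos)),
    )


def metric_report(scores, labels, n_features_used: int,
                  prc_estimator: str = "average_precision") -> MetricReport:
    cc = confusion_from_scores(scores, labels)
    gmean, f1 = threshold_metrics(cc)
    return MetricReport(gmean, f1, auc_roc(scores, labels),
                        auc_prc(scores, labels, prc_estimator),
                        n_features_used, cc)


def _make_classifier(classifier_cfg, seed):
    cfg = dict(n_estimators=500)
    cfg.update(classifier_cfg or {})
    return RandomForestClassifier(random_state=seed, **cfg)


def oof_scores(tbl: FeatureTable, feature_idx, folds=5, classifier_cfg=None,
               random_state=None, train_resampler=None) -> np.ndarray:
    """Out-of-fold positive-class probabilities on selected features.

    ``train_resampler``, if given, is a sampler with ``fit_resample`` that
    is applied to each training fold only (no information from the held-out
    fold leaks into the synthetic rows).
    """
    feature_idx = np.asarray(feature_idx, dtype=int)
    if min(tbl.n1, tbl.n2) < folds:
        raise ValueError(
            f"cannot stratify {folds} folds: minority class has {tbl.n1} samples"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=random_state)
    out = np.empty(tbl.n)
    for i, (tr, te) in enumerate(skf.split(tbl.X, tbl.y)):
        Xtr, ytr = tbl.X[tr], tbl.y[tr]
        if train_resampler is not None:
            res = train_resampler.fit_resample(
                FeatureTable(Xtr, ytr, tbl.feature_names))
            Xtr, ytr = res.table.X, res.table.y
        clf = _make_classifier(classifier_cfg, None if random_state is None
                               else random_state + i)
        clf.fit(Xtr[:, feature_idx], ytr)
        pos_col = int(np.nonzero(clf.classes_ == 1)[0][0])
        out[te] = clf.predict_proba(tbl.X[te][:, feature_idx])[:, pos_col]
    return out


def select_top_k_cv(tbl: FeatureTable, rank: RankList, folds: int = 5,
                    classifier_cfg=None, random_state=None,
                    train_resampler=None, max_k=None):
    """Cross-validated search for the optimal number of top-ranked features.

    For k = 1..p the features are restricted to the top-k of ``rank`` and
    the mean out-of-fold AUCPRC over stratified folds is computed with a
    random-forest classifier (500 trees by default). Returns
    ``(k_opt, curve)`` where ``curve`` is a DataFrame with columns
    ``k, mean_aucprc, sd_aucprc`` and ``k_opt`` is the smallest maximizer.
    """
    p = rank.p
    if p != tbl.p:
        raise ValueError("ranking does not match the table's feature count")
    if min(tbl.n1, tbl.n2) < folds:
        raise ValueError(
            f"cannot stratify {folds} folds: minority class has {tbl.n1} samples"
        )
    kmax = p if max_k is None else min(int(max_k), p)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=random_state)
    splits = list(skf.split(tbl.X, tbl.y))
    means, sds = [], []
    for k in range(1, kmax + 1):
        idx = rank.order[:k]
        vals = []
        for i, (tr, te) in enumerate(splits):
            Xtr, ytr = tbl.X[tr], tbl.y[tr]
            if train_resampler is not None:
                res = train_resampler.fit_resample(
                    FeatureTable(Xtr, ytr, tbl.feature_names))
                Xtr, ytr = res.table.X, res.table.y
            clf = _make_classifier(classifier_cfg, None if random_state is None
                                   else random_state + i)
            clf.fit(Xtr[:, idx], ytr)
            pos_col = int(np.nonzero(clf.classes_ == 1)[0][0])
            s = clf.predict_proba(tbl.X[te][:, idx])[:, pos_col]
            vals.append(auc_prc(s, tbl.y[te]))
        means.append(float(np.mean(vals)))
        sds.append(float(np.std(vals, ddof=1)))
    curve = pd.DataFrame({"k": np.arange(1, kmax + 1),
                          "mean_aucprc": means, "sd_aucprc": sds})
    k_opt = int(curve["k"][np.argmax(curve["mean_aucprc"].to_numpy())])
    return k_opt, curve


def rowmax_proportion(results_table: pd.DataFrame, focal_column: str,
                      comparison_columns, row_filter=None):
    """Count rows where the focal column reaches the row maximum (≥).

    ``row_filter`` is an optional boolean mask or predicate applied to the
    table first. Rows with a missing focal value, or with every comparison
    value missing, are skipped with a warning. Returns
    ``(count, n_rows, proportion)``.
    """
    df = results_table
    if row_filter is not None:
        mask = row_filter(df) if callable(row_filter) else np.asarray(row_filter)
        df = df.loc[mask]
    missing = [c for c in [focal_column, *comparison_columns] if c not in df.columns]
    if missing:
        raise ValueError(f"columns not found: {missing}")
    focal = pd.to_numeric(df[focal_column], errors="coerce")
    comp = df[list(comparison_columns)].apply(pd.to_numeric, errors="coerce")
    usable = focal.notna() & comp.notna().any(axis=1)
    if not usable.all():
        warnings.warn(f"skipping {int((~usable).sum())} rows with missing cells")
    focal, comp = focal[usable], comp[usable]
    count = int((focal >= comp.max(axis=1)).sum())
    n = int(usable.sum())
    return count, n, count / n if n else float("nan")
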