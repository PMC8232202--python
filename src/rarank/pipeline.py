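"""End-to-end RAR runs and the method-comparison table summaries.

:func:`run_rar` executes the full workflow on one feature table —
re-balance, eight filter rankings, consensus aggregation, cross-validated
top-k search, metrics at the chosen k — and persists every intermediate
artifact (re-balanced table, rank lists, aggregation report, AUCPRC
curve, JSON report) so each reported number can be recomputed from the
saved pieces. A single global seed fans out to per-stage child seeds.

:func:`summarize_tables` applies the row-maximum counting rules to
benchmark tables shaped like the packaged fixtures (rows = dataset ×
re-balance case; columns = consensus methods and the eight filters) and
reports, for each metric table and pooled:

* case-1 rows of imbalanced datasets: how often plain rank aggregation
  (RA) reaches the row maximum of the eight filters;
* case 2–7 rows: how often re-balanced aggregation (RAR) reaches the row
  maximum of the eight filters;
* case 2–7 rows: how often RAR is at least the same dataset's case-1 RA.

Ties count as reaching the maximum.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .aggregation import CEConfig, aggregate_ce, mean_pairwise_tau
from .evaluation import (metric_report, oof_scores, rowmax_proportion,
                         select_top_k_cv)
from .filters import FILTER_METHODS, rank_all_filters
from .resampling import ResamplePlan, apply_case
from .table import FeatureTable, read_feature_table, write_feature_table

__all__ = ["RunConfig", "RunReport", "run_rar", "summarize_tables",
           "load_fixture_tables", "METRIC_TABLES"]

METRIC_TABLES = ("gmean", "f1", "aucroc", "aucprc")


@dataclass
class RunConfig:
    """Fully serializable configuration of one RAR run."""

    input_path: str
    label_column: str = "label"
    positive_label: str | None = None
    case_id: int = 1
    seed: int | None = 0
    relieff_k: int = 10
    r_value_k: int = 5
    smote_k: int = 5
    ce_samples: int | None = None
    ce_elite: float = 0.1
    ce_smoothing: float = 0.7
    ce_max_iters: int = 100
    ce_window: int = 5
    cv_folds: int = 5
    n_estimators: int = 500
    resample_in_folds: bool = True
    output_dir: str = "rar_output"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class RunReport:
    config_hash: str
    seeds: dict
    counts_before: tuple
    counts_after: tuple
    filter_rankings: dict
    consensus: list
    objective: float
    mean_pairwise_tau: float
    k_opt: int
    curve: pd.DataFrame
    metrics: dict
    output_dir: str | None = None
    extras: dict = field(default_factory=dict)


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def run_rar(cfg: RunConfig, table: FeatureTable | None = None) -> RunReport:
    """Run re-balance → rank → aggregate → top-k CV → metrics.

    ``table`` may be passed directly (e.g. a synthetic table); otherwise
    it is read from ``cfg.input_path``. With ``cfg.resample_in_folds``
    (the default) the evaluation re-applies the re-balance case inside
    each training fold of the CV so no synthetic information leaks into
    held-out folds; switching it off evaluates directly on the re-balanced
    table, reproducing the workflow the benchmark tables describe.
    """
    if table is None:
        table = read_feature_table(cfg.input_path, cfg.label_column,
                                   cfg.positive_label)
    root = np.random.SeedSequence(cfg.seed)
    s_resample, s_ce, s_cv = (_child_seed(c) for c in root.spawn(3))

    stage = "resample"
    try:
        plan = ResamplePlan(cfg.case_id, rng_seed=s_resample, smote_k=cfg.smote_k)
        res = apply_case(table, plan)
        work = res.table

        stage = "rank"
        rankings = rank_all_filters(work, relieff_k=cfg.relieff_k,
                                    r_value_k=cfg.r_value_k)
        tau_bar = mean_pairwise_tau(rankings)

        stage = "aggregate"
        agg = aggregate_ce(rankings, config=CEConfig(
            cfg.ce_samples, cfg.ce_elite, cfg.ce_smoothing,
            cfg.ce_max_iters, cfg.ce_window, s_ce))

        stage = "select_k"
        if cfg.resample_in_folds:
            from .resampling import CaseResampler
            eval_tbl = table
            sampler = (None if cfg.case_id == 1 else
                       CaseResampler(cfg.case_id, cfg.smote_k,
                                     random_state=s_resample))
        else:
            eval_tbl, sampler = work, None
        k_opt, curve = select_top_k_cv(
            eval_tbl, agg.optimal_list, folds=cfg.cv_folds,
            classifier_cfg={"n_estimators": cfg.n_estimators},
            random_state=s_cv, train_resampler=sampler)

        stage = "metrics"
        scores = oof_scores(eval_tbl, agg.optimal_list.order[:k_opt],
                            folds=cfg.cv_folds,
                            classifier_cfg={"n_estimators": cfg.n_estimators},
                            random_state=s_cv, train_resampler=sampler)
        rep = metric_report(scores, eval_tbl.y, k_opt)
    except Exception as exc:
        raise RuntimeError(f"RAR stage {stage!r} failed: {exc}") from exc

    names = table.feature_names
    report = RunReport(
        config_hash=cfg.digest(),
        seeds={"resample": s_resample, "ce": s_ce, "cv": s_cv},
        counts_before=res.counts_before,
        counts_after=res.counts_after,
        filter_rankings={m: [names[j] for j in r.order]
                         for m, r in zip(FILTER_METHODS, rankings)},
        consensus=[names[j] for j in agg.optimal_list.order],
        objective=agg.objective,
        mean_pairwise_tau=tau_bar,
        k_opt=k_opt,
        curve=curve,
        metrics={"gmean": rep.gmean, "f1": rep.f1,
                 "auc_roc": rep.auc_roc, "auc_prc": rep.auc_prc},
    )

    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.output_dir = str(out)
    write_feature_table(res.table, out / "resampled.csv",
                        provenance=res.synthetic)
    ranks_df = pd.DataFrame(
        {m: r.ranks for m, r in zip(FILTER_METHODS, rankings)},
        index=list(names))
    ranks_df["consensus"] = agg.optimal_list.ranks
    ranks_df["mean_rank"] = ranks_df[list(FILTER_METHODS)].mean(axis=1)
    ranks_df.sort_values("consensus").to_csv(out / "ranks.csv",
                                             index_label="feature")
    curve.to_csv(out / "aucprc_curve.csv", index=False)
    cfg.to_yaml(out / "config.yaml")
    with open(out / "report.json", "w") as fh:
        json.dump({
            "config_hash": report.config_hash, "seeds": report.seeds,
            "counts_before": list(report.counts_before),
            "counts_after": list(report.counts_after),
            "mean_pairwise_tau": tau_bar,
            "objective": agg.objective, "k_opt": k_opt,
            "consensus": report.consensus, "metrics": report.metrics,
        }, fh, indent=2)
    return report


# ---------------------------------------------------------------------------
# benchmark-table summaries
# ---------------------------------------------------------------------------

def load_fixture_tables(paths=None) -> dict:
    """Load the packaged benchmark metric tables (or user-supplied CSVs)."""
    out = {}
    for name in METRIC_TABLES:
        if paths is not None and name in paths:
            out[name] = pd.read_csv(paths[name])
        else:
            with resources.files("rarank.data").joinpath(f"{name}.csv").open() as fh:
                out[name] = pd.read_csv(fh)
        missing = [c for c in ("dataset", "case", "RA", "RAR", *FILTER_METHODS)
                   if c not in out[name].columns]
        if missing:
            raise ValueError(f"fixture table {name!r} lacks columns {missing}")
    return out


def load_dataset_summary() -> pd.DataFrame:
    """The five-dataset summary (sizes and imbalance ratios)."""
    with resources.files("rarank.data").joinpath("datasets.csv").open() as fh:
        return pd.read_csv(fh)


def summarize_tables(tables: dict | None = None,
                     balanced_datasets=("NPC",)) -> dict:
    """The three row-maximum comparisons, per metric table and pooled."""
    tables = tables if tables is not None else load_fixture_tables()
    filters = list(FILTER_METHODS)
    pooled = {k: [0, 0] for k in
              ("ra_vs_filters_case1", "rar_vs_filters_cases2_7", "rar_vs_ra")}
    per_table = {}
    for name, df in tables.items():
        df = df.copy()
        df["case"] = df["case"].astype(int)
        imb = ~df["dataset"].isin(balanced_datasets)

        c1, n1_, _ = rowmax_proportion(df, "RA", filters,
                                       row_filter=(df["case"] == 1) & imb)
        c2, n2_, _ = rowmax_proportion(df, "RAR", filters,
                                       row_filter=df["case"] > 1)
        ra_by_ds = df.loc[df["case"] == 1].set_index("dataset")["RA"]
        sub = df.loc[df["case"] > 1].copy()
        sub["RA_case1"] = sub["dataset"].map(ra_by_ds)
        c3, n3_, _ = rowmax_proportion(sub, "RAR", ["RA_case1"])

        per_table[name] = {
            "ra_vs_filters_case1": (c1, n1_),
            "rar_vs_filters_cases2_7": (c2, n2_),
            "rar_vs_ra": (c3, n3_),
        }
        for key, (c, n) in per_table[name].items():
            pooled[key][0] += c
            pooled[key][1] += n

    result = {"per_table": per_table, "pooled": {}}
    for key, (c, n) in pooled.items():
        result["pooled"][key] = {
            "count": c, "n": n, "percent": round(100.0 * c / n, 2)}
    return result
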