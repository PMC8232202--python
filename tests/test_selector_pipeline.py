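import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner
from sklearn.base import clone
from sklearn.pipeline import Pipeline
from sklearn.linear_model import LogisticRegression

from rarank import (RARSelector, RunConfig, run_rar, summarize_tables,
                    write_feature_table)
from rarank.cli import main as cli_main
from rarank.pipeline import load_dataset_summary, load_fixture_tables


def make_informative(n1=20, n2=40, p=6, seed=0):
    g = np.random.default_rng(seed)
    X = g.normal(0, 1, (n1 + n2, p))
    X[:n1, 0] += 3.0
    X[:n1, 1] += 2.0
    y = np.array([1] * n1 + [0] * n2)
    return X, y


def test_selector_sklearn_contract():
    sel = RARSelector(case=6, n_features_to_select=2, random_state=0)
    params = sel.get_params()
    assert params["case"] == 6
    cloned = clone(sel)
    assert cloned.get_params() == params


def test_selector_ranks_informative_features_first():
    X, y = make_informative()
    sel = RARSelector(random_state=1).fit(X, y)
    assert set(sel.ranking_.order[:2].tolist()) == {0, 1}
    assert len(sel.filter_rankings_) == 8
    # no selection requested: transform keeps everything
    assert sel.transform(X).shape == X.shape


def test_selector_top_k_transform_and_mask():
    X, y = make_informative(seed=3)
    sel = RARSelector(n_features_to_select=2, random_state=2).fit(X, y)
    Xt = sel.transform(X)
    assert Xt.shape == (60, 2)
    assert sel.get_support().sum() == 2
    assert sel.get_support()[[0, 1]].all()


def test_selector_cv_choice_small():
    X, y = make_informative(n1=15, n2=25, p=4, seed=4)
    sel = RARSelector(n_features_to_select="cv", n_estimators=30,
                      random_state=3).fit(X, y)
    assert 1 <= sel.k_opt_ <= 4
    assert len(sel.cv_curve_) == 4


def test_selector_resample_case_applied():
    X, y = make_informative(n1=10, n2=30, seed=5)
    sel = RARSelector(case=6, random_state=4).fit(X, y)
    assert sel.resample_.counts_after == (10, 10)


def test_selector_in_sklearn_pipeline():
    X, y = make_informative(seed=6)
    pipe = Pipeline([
        ("select", RARSelector(n_features_to_select=2, random_state=0)),
        ("clf", LogisticRegression(max_iter=200)),
    ]).fit(X, y)
    assert pipe.score(X, y) > 0.9


def test_selector_deterministic_given_state():
    X, y = make_informative(seed=7)
    a = RARSelector(case=2, random_state=11).fit(X, y)
    b = RARSelector(case=2, random_state=11).fit(X, y)
    assert a.ranking_.order.tolist() == b.ranking_.order.tolist()
    np.testing.assert_array_equal(a.resample_.table.X, b.resample_.table.X)


# -- run_rar ---------------------------------------------------------------

def _write_demo_table(path, seed=0):
    from rarank import FeatureTable
    X, y = make_informative(n1=12, n2=28, p=4, seed=seed)
    write_feature_table(FeatureTable(X, y), path)


def test_run_rar_end_to_end_and_determinism(tmp_path):
    csv = tmp_path / "demo.csv"
    _write_demo_table(csv)
    cfg = dict(input_path=str(csv), case_id=6, seed=42, n_estimators=40,
               cv_folds=4)
    r1 = run_rar(RunConfig(output_dir=str(tmp_path / "o1"), **cfg))
    r2 = run_rar(RunConfig(output_dir=str(tmp_path / "o2"), **cfg))
    assert r1.consensus == r2.consensus
    assert r1.metrics == r2.metrics
    assert r1.k_opt == r2.k_opt
    assert r1.config_hash != ""  # persisted artifacts exist
    for name in ("resampled.csv", "ranks.csv", "aucprc_curve.csv",
                 "report.json", "config.yaml"):
        assert (tmp_path / "o1" / name).exists()
    saved = json.loads((tmp_path / "o1" / "report.json").read_text())
    assert saved["k_opt"] == r1.k_opt
    assert saved["metrics"] == r1.metrics


def test_run_rar_can_evaluate_on_rebalanced_table(tmp_path):
    csv = tmp_path / "demo.csv"
    _write_demo_table(csv, seed=1)
    cfg = RunConfig(input_path=str(csv), case_id=6, seed=0, n_estimators=30,
                    cv_folds=3, resample_in_folds=False,
                    output_dir=str(tmp_path / "out"))
    rep = run_rar(cfg)
    # evaluation ran on the re-balanced (10/10... here 12/12) table
    assert rep.counts_after[0] == rep.counts_after[1]


def test_run_config_yaml_round_trip(tmp_path):
    cfg = RunConfig(input_path="x.csv", case_id=3, seed=7)
    path = tmp_path / "cfg.yaml"
    cfg.to_yaml(path)
    assert RunConfig.from_yaml(path) == cfg
    assert cfg.digest() == RunConfig.from_yaml(path).digest()


# -- fixtures and summaries -------------------------------------------------

def test_fixture_tables_well_formed():
    tables = load_fixture_tables()
    assert set(tables) == {"gmean", "f1", "aucroc", "aucprc"}
    for name, df in tables.items():
        assert len(df) == 29  # 1 NPC row + 4 datasets x 7 cases
        assert df.loc[df["case"] == 1, "RAR"].isna().all()
        assert df.loc[df["case"] > 1, "RA"].isna().all()


def test_summarize_tables_counts():
    out = summarize_tables()
    pooled = out["pooled"]
    assert pooled["ra_vs_filters_case1"]["n"] == 16
    assert pooled["rar_vs_filters_cases2_7"]["n"] == 96
    assert pooled["rar_vs_ra"]["n"] == 96
    for key in pooled:
        assert 0 <= pooled[key]["percent"] <= 100


def test_dataset_summary_ratio_is_majority_over_minority():
    df = load_dataset_summary()
    # printed ratios use half-up rounding to two decimals (21/8 -> 2.63)
    recomputed = np.floor(df["majority"] / df["minority"] * 100 + 0.5) / 100
    pd.testing.assert_series_equal(recomputed, df["ratio"], check_names=False)


# -- CLI -------------------------------------------------------------------

def test_cli_rank_and_simulate(tmp_path):
    csv = tmp_path / "demo.csv"
    _write_demo_table(csv, seed=2)
    runner = CliRunner()
    res = runner.invoke(cli_main, ["rank", str(csv)])
    assert res.exit_code == 0, res.output
    assert "t_test" in res.output

    res = runner.invoke(cli_main, ["simulate", "--n-total", "48",
                                   "--repeats", "2", "--ratios", "1,3"])
    assert res.exit_code == 0, res.output
    assert "mean_tau" in res.output


def test_cli_resample_and_summarize(tmp_path):
    csv = tmp_path / "demo.csv"
    _write_demo_table(csv, seed=3)
    out = tmp_path / "res.csv"
    runner = CliRunner()
    res = runner.invoke(cli_main, ["resample", str(csv), "--case", "6",
                                   "-o", str(out)])
    assert res.exit_code == 0, res.output
    df = pd.read_csv(out)
    assert (df["label"] == 1).sum() == (df["label"] == 0).sum()

    res = runner.invoke(cli_main, ["summarize-tables"])
    assert res.exit_code == 0, res.output
    assert json.loads(res.output)["pooled"]["rar_vs_ra"]["count"] == 93
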