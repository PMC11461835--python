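"""Model zoo construction, metric algebra, CV fold hygiene."""

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import GradientBoostingClassifier

from somnaug.classify import (
    build_models,
    holdout_eval,
    kfold_cv,
    make_subject_folds,
    metrics_from_confusion,
    subjectwise_cv,
)
from somnaug.features import FEATURE_COLUMNS


def _toy_table(n_per_class=60, n_subjects=6, gap=3.0, seed=0):
    """Feature table with a separable alpha_band_power and noise elsewhere."""
    rng = np.random.default_rng(seed)
    rows = []
    for label, offset in (("insomnia", gap), ("healthy", 0.0)):
        for i in range(n_per_class):
            row = {c: rng.normal() for c in FEATURE_COLUMNS}
            row["alpha_band_power"] = rng.normal(offset, 1.0)
            row["label"] = label
            row["subject_id"] = f"{label[:3]}{i % n_subjects}"
            row["provenance"] = "synthetic"
            rows.append(row)
    return pd.DataFrame(rows)


# -------------------------------------------------------------- model zoo

def test_five_models_with_fixed_hyperparameters():
    specs = build_models()
    assert [s.name for s in specs] == ["DT", "EBDT", "GB", "RF", "SC"]
    by_name = {s.name: s.estimator for s in specs}
    assert by_name["DT"].random_state == 22
    assert by_name["DT"].max_depth == 10
    assert by_name["DT"].criterion == "entropy"
    assert by_name["EBDT"].n_estimators == 100
    assert by_name["EBDT"].estimator.criterion == "entropy"
    assert by_name["GB"].n_estimators == 100
    assert by_name["GB"].learning_rate == 0.1
    assert by_name["RF"].n_estimators == 100
    for name in ("EBDT", "GB", "RF"):
        assert by_name[name].random_state == 22
    assert isinstance(by_name["SC"].final_estimator, GradientBoostingClassifier)
    assert [n for n, _ in by_name["SC"].estimators] == ["EBDT", "RF", "DT"]


# --------------------------------------------------------------- metrics

def test_constructed_confusion_matrix_metrics():
    """TP=45, FN=5, TN=40, FP=10 reproduces the standard formula values."""
    r = metrics_from_confusion(tp=45, fn=5, tn=40, fp=10)
    assert r.sensitivity == pytest.approx(0.90)
    assert r.specificity == pytest.approx(0.80)
    assert r.precision == pytest.approx(45 / 55)
    assert r.accuracy == pytest.approx(0.85)
    assert r.f1 == pytest.approx(2 * (45 / 55) * 0.9 / ((45 / 55) + 0.9))
    assert r.cer == pytest.approx(0.15)
    assert r.recall == r.sensitivity


def test_cer_identity_and_f1_harmonic_mean_on_reports():
    table = _toy_table()
    for rep in holdout_eval(table).values():
        assert rep.cer == pytest.approx(1.0 - rep.accuracy, abs=1e-12)
        if rep.precision + rep.recall > 0:
            hm = 2 * rep.precision * rep.recall / (rep.precision + rep.recall)
            assert rep.f1 == pytest.approx(hm, abs=1e-12)
        c = rep.confusion
        total = sum(c.values())
        assert rep.accuracy == pytest.approx((c["TP"] + c["TN"]) / total)
        assert 0.0 <= rep.auc <= 1.0


# ---------------------------------------------------------------- holdout

def test_perfectly_separable_table_scores_one():
    table = _toy_table(gap=50.0)
    rep = holdout_eval(table)["RF"]
    assert rep.accuracy == 1.0
    assert rep.cer == 0.0


def test_single_class_table_rejected():
    table = _toy_table()
    with pytest.raises(ValueError, match="both classes"):
        holdout_eval(table[table["label"] == "healthy"])


def test_label_permutation_gives_chance_auc():
    rng = np.random.default_rng(22)
    table = _toy_table(n_per_class=300, gap=3.0, seed=1)
    table["label"] = rng.permutation(table["label"].to_numpy())
    rep = holdout_eval(table)["RF"]
    assert rep.auc == pytest.approx(0.5, abs=0.1)


# ------------------------------------------------------------------ k-fold

def test_kfold_partition_arithmetic():
    table = _toy_table(n_per_class=50)  # 100 rows
    out = kfold_cv(table, k=5, models=build_models()[:1])
    scores = out["DT"]["fold_scores"]
    assert len(scores) == 5
    assert out["DT"]["mean"] == pytest.approx(np.mean(scores))


def test_kfold_perfect_separation():
    table = _toy_table(gap=50.0)
    out = kfold_cv(table, k=5, models=[m for m in build_models() if m.name == "RF"])
    assert out["RF"]["mean"] == 1.0


def test_kfold_too_many_folds_rejected():
    with pytest.raises(ValueError):
        kfold_cv(_toy_table(n_per_class=2), k=50)


# ------------------------------------------------------------ subject-wise

def test_subject_folds_pair_classes():
    table = _toy_table(n_subjects=6)
    groups = make_subject_folds(table, folds=6)
    assert len(groups) == 6
    for g in groups:
        labels = {table.loc[table["subject_id"] == s, "label"].iloc[0] for s in g}
        assert labels == {"insomnia", "healthy"}


def test_subjectwise_no_leakage():
    table = _toy_table(n_subjects=6)
    out = subjectwise_cv(table, folds=6, models=build_models()[:1])
    groups = out["DT"]["fold_subjects"]
    all_held = [s for g in groups for s in g]
    assert sorted(all_held) == sorted(table["subject_id"].unique())
    assert len(all_held) == len(set(all_held))  # each subject tested once


def test_subjectwise_ctgan_rows_train_only():
    """Rows tagged ctgan join training folds but are never tested."""
    table = _toy_table(n_subjects=6)
    extra = table.iloc[:20].copy()
    extra["subject_id"] = "ctgan"
    extra["provenance"] = "ctgan"
    combined = pd.concat([table, extra], ignore_index=True)
    out = subjectwise_cv(combined, folds=6, models=build_models()[:1])
    groups = out["DT"]["fold_subjects"]
    assert all("ctgan" not in g for g in groups)
    n_tested = sum(
        (combined["subject_id"].isin(g)).sum() for g in groups
    )
    assert n_tested == len(table)  # every attributed row tested exactly once


def test_subjectwise_too_few_subjects_rejected():
    table = _toy_table(n_subjects=2)
    with pytest.raises(ValueError):
        subjectwise_cv(table, folds=10)


def test_leave_one_subject_out_degenerate():
    table = _toy_table(n_subjects=3)  # 6 distinct subjects across classes
    out = subjectwise_cv(table, folds=6, models=build_models()[:1])
    assert all(len(g) == 1 for g in out["DT"]["fold_subjects"])
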