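"""Five tree-based classifiers and holdout / k-fold / subject-wise evaluation.

Model zoo (fixed hyperparameters, random_state 22 throughout):

* DT   — decision tree, entropy criterion, max depth 10
* EBDT — bagging over 100 entropy decision trees
* GB   — gradient boosting, 100 estimators, learning rate 0.1
* RF   — random forest, 100 estimators
* SC   — stacking of {EBDT, RF, DT} with a GB meta-learner

Reported metrics: accuracy, sensitivity (= recall of the insomnia class),
specificity, precision, recall, F1, AUC and the classification error rate
CER = 1 − accuracy.  The insomnia class is the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import (
    BaggingClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
    StackingClassifier,
)
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_COLUMNS
from .preprocessing import BANDS

RANDOM_STATE = 22
POSITIVE = "insomnia"


@dataclass
class ModelSpec:
    name: str
    estimator: object


def build_models(random_state: int = RANDOM_STATE) -> list[ModelSpec]:
    """The five classifiers with their fixed hyperparameters."""
    dt = DecisionTreeClassifier(
        random_state=random_state, max_depth=10, criterion="entropy"
    )
    ebdt = BaggingClassifier(
        estimator=DecisionTreeClassifier(criterion="entropy"),
        n_estimators=100,
        random_state=random_state,
    )
    gb = GradientBoostingClassifier(
        random_state=random_state, n_estimators=100, learning_rate=0.1
    )
    rf = RandomForestClassifier(random_state=random_state, n_estimators=100)
    sc = StackingClassifier(
        estimators=[("EBDT", clone(ebdt)), ("RF", clone(rf)), ("DT", clone(dt))],
        final_estimator=clone(gb),
    )
    return [
        ModelSpec("DT", dt),
        ModelSpec("EBDT", ebdt),
        ModelSpec("GB", gb),
        ModelSpec("RF", rf),
        ModelSpec("SC", sc),
    ]


@dataclass
class EvalReport:
    """Per-model binary-classification metrics (all fractions in [0, 1])."""

    model: str
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    recall: float
    f1: float
    auc: float
    cer: float
    confusion: dict[str, int]
    fold_scores: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
            "cer": self.cer,
            "confusion": self.confusion,
            "fold_scores": self.fold_scores,
        }


def metrics_from_confusion(
    tp: int, fn: int, tn: int, fp: int, auc: float = float("nan"),
    model: str = "manual",
) -> EvalReport:
    """All ratio metrics from raw confusion counts (AUC passed through)."""
    total = tp + fn + tn + fp
    if total == 0:
        raise ValueError("empty confusion matrix")
    acc = (tp + tn) / total
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    return EvalReport(
        model=model,
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        recall=sens,
        f1=f1,
        auc=auc,
        cer=1.0 - acc,
        confusion={"TP": int(tp), "FP": int(fp), "TN": int(tn), "FN": int(fn)},
    )


def _band_columns(band: str) -> list[str]:
    if band == "combined":
        return list(FEATURE_COLUMNS)
    if band not in BANDS:
        raise ValueError(f"unknown band {band!r}")
    return [c for c in FEATURE_COLUMNS if c.startswith(f"{band}_")]


def _xy(table: pd.DataFrame, band: str = "combined"):
    cols = _band_columns(band)
    X = table[cols].to_numpy(dtype=np.float64)
    y = (table["label"].astype(str) == POSITIVE).astype(int).to_numpy()
    return X, y


def _evaluate(est, X_test, y_test, model_name: str) -> EvalReport:
    pred = est.predict(X_test)
    tp = int(np.sum((pred == 1) & (y_test == 1)))
    fn = int(np.sum((pred == 0) & (y_test == 1)))
    tn = int(np.sum((pred == 0) & (y_test == 0)))
    fp = int(np.sum((pred == 1) & (y_test == 0)))
    if len(np.unique(y_test)) == 2:
        score = est.predict_proba(X_test)[:, list(est.classes_).index(1)]
        auc = float(roc_auc_score(y_test, score))
    else:
        auc = float("nan")
    return metrics_from_confusion(tp, fn, tn, fp, auc=auc, model=model_name)


def holdout_eval(
    table: pd.DataFrame,
    test_fraction: float = 0.25,
    band: str = "combined",
    models: list[ModelSpec] | None = None,
    random_state: int = RANDOM_STATE,
) -> dict[str, EvalReport]:
    """Stratified 75/25 holdout evaluation of every model."""
    X, y = _xy(table, band)
    if len(np.unique(y)) < 2:
        raise ValueError("holdout evaluation needs both classes present")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_fraction, stratify=y, random_state=random_state
    )
    reports = {}
    for spec in models or build_models(random_state):
        est = clone(spec.estimator)
        est.fit(X_tr, y_tr)
        reports[spec.name] = _evaluate(est, X_te, y_te, spec.name)
    return reports


def kfold_cv(
    table: pd.DataFrame,
    k: int = 5,
    band: str = "combined",
    models: list[ModelSpec] | None = None,
    random_state: int = RANDOM_STATE,
) -> dict[str, dict]:
    """Stratified k-fold cross-validation accuracies."""
    X, y = _xy(table, band)
    if k > len(y):
        raise ValueError(f"k={k} exceeds the {len(y)} available rows")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=random_state)
    out = {}
    for spec in models or build_models(random_state):
        scores = []
        for tr, te in skf.split(X, y):
            est = clone(spec.estimator)
            est.fit(X[tr], y[tr])
            scores.append(float(np.mean(est.predict(X[te]) == y[te])))
        out[spec.name] = {"fold_scores": scores, "mean": float(np.mean(scores))}
    return out


def make_subject_folds(table: pd.DataFrame, folds: int = 6) -> list[list[str]]:
    """Pair one insomnia with one healthy subject per fold where possible.

    Subjects are taken from rows whose ``subject_id`` is a real subject
    (synthetic "ctgan" rows carry no subject).  With equal per-class
    subject counts equal to ``folds``, each fold holds exactly one subject
    of each class; otherwise subjects are dealt round-robin per class.
    """
    sub = table[table["subject_id"] != "ctgan"]
    by_class: dict[str, list[str]] = {}
    for label, grp in sub.groupby("label"):
        by_class[str(label)] = sorted(grp["subject_id"].unique())
    n_subjects = sum(len(v) for v in by_class.values())
    if n_subjects < folds:
        raise ValueError(f"{n_subjects} subject groups < {folds} folds")
    groups: list[list[str]] = [[] for _ in range(folds)]
    k = 0  # global counter so every fold is non-empty even with few subjects
    for subjects in by_class.values():
        for s in subjects:
            groups[k % folds].append(s)
            k += 1
    return groups


def subjectwise_cv(
    table: pd.DataFrame,
    folds: int = 6,
    band: str = "combined",
    models: list[ModelSpec] | None = None,
    random_state: int = RANDOM_STATE,
) -> dict[str, dict]:
    """Subject-wise cross-validation: no subject straddles train and test.

    Rows without a subject attribution (CTGAN-generated, subject_id
    "ctgan") are appended to every training fold and never tested on.
    """
    if "subject_id" not in table.columns:
        raise ValueError("subject-wise CV needs a subject_id column")
    groups = make_subject_folds(table, folds)
    cols = _band_columns(band)
    y_all = (table["label"].astype(str) == POSITIVE).astype(int).to_numpy()
    X_all = table[cols].to_numpy(dtype=np.float64)
    subject = table["subject_id"].astype(str).to_numpy()
    out = {}
    for spec in models or build_models(random_state):
        scores = []
        for heldout in groups:
            te = np.isin(subject, heldout)
            tr = ~te
            est = clone(spec.estimator)
            est.fit(X_all[tr], y_all[tr])
            scores.append(float(np.mean(est.predict(X_all[te]) == y_all[te])))
        out[spec.name] = {
            "fold_scores": scores,
            "mean": float(np.mean(scores)),
            "fold_subjects": groups,
        }
    return out
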