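"""Stratified cross-validated evaluation of the five ensemble methods.

Methods: ``mv-lda``/``mv-svm`` (plurality voting over six single-feature
LDA or SVM base classifiers), ``wv-lda``/``wv-svm`` (weighted majority
voting with cross-trained per-class confidence weights), and ``lgbm``
(multiclass LightGBM on the concatenated features).

Evaluation pools held-out predictions across K stratified folds into
one confusion matrix, from which per-class recall, overall accuracy and
the macro-F1 score — the harmonic mean of macro-averaged precision and
macro-averaged recall (note: not the mean of per-class F1 scores) — are
computed, along with mean wall-clock training and prediction times.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import ensemble
from .features import SELECTED_FEATURES

METHODS = ("mv-lda", "mv-svm", "wv-lda", "wv-svm", "lgbm")


@dataclass
class FoldPlan:
    """Row-to-fold assignment with per-class balance within one."""

    k: int
    assignments: np.ndarray
    seed: int


@dataclass
class EvalReport:
    """Pooled-confusion evaluation summary for one method."""

    method: str
    confusion: np.ndarray
    per_class_accuracy: np.ndarray
    overall_accuracy: float
    macro_f1: float
    t_train: float
    t_predict: float
    seed: int
    labels: np.ndarray = field(default_factory=lambda: np.arange(1, 13))


def stratified_folds(labels: np.ndarray, k: int = 5, seed: int = 0) -> FoldPlan:
    """Stratified fold assignment; per-class counts differ by <= 1 across folds."""
    labels = np.asarray(labels)
    counts = pd.Series(labels).value_counts()
    if counts.min() < k:
        raise ValueError(f"smallest class has {counts.min()} members (< k={k})")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.empty(labels.shape[0], dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(labels.shape[0]), labels)):
        assignments[test_idx] = fold
    return FoldPlan(k=k, assignments=assignments, seed=seed)


def confusion_matrix(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int = 12
) -> np.ndarray:
    """(L, L) count matrix, rows = true class, cols = predicted class."""
    cm = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(np.asarray(y_true), np.asarray(y_pred)):
        cm[int(t) - 1, int(p) - 1] += 1
    return cm


def macro_f1(confusion: np.ndarray) -> float:
    """Harmonic mean of macro-precision and macro-recall.

    Classes that are never predicted contribute precision 0; classes
    with zero true count are excluded from both averages. Note this is
    not the average of per-class F1 scores (the two differ whenever
    precision and recall are unbalanced differently across classes).
    """
    cm = np.asarray(confusion, dtype=float)
    if cm.sum() == 0:
        raise ValueError("empty confusion matrix")
    true_counts = cm.sum(axis=1)
    pred_counts = cm.sum(axis=0)
    keep = true_counts > 0
    diag = np.diag(cm)
    recall = np.where(keep, np.divide(diag, true_counts, where=keep, out=np.zeros_like(diag)), 0.0)
    precision = np.where(pred_counts > 0, np.divide(diag, pred_counts, where=pred_counts > 0, out=np.zeros_like(diag)), 0.0)
    l_eff = int(keep.sum())
    macro_p = float(precision[keep].sum() / l_eff)
    macro_r = float(recall[keep].sum() / l_eff)
    if macro_p + macro_r == 0:
        return 0.0
    return 2.0 * macro_p * macro_r / (macro_p + macro_r)


def _fit_predict(
    method: str,
    train: pd.DataFrame,
    test: pd.DataFrame,
    feature_names: tuple[str, ...],
    seed: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, float]:
    """Train on ``train``, predict ``test``; returns (preds, t_train, t_pred)."""
    if method == "lgbm":
        t0 = time.perf_counter()
        model = ensemble.train_gbm(train, feature_names, seed=seed)
        t1 = time.perf_counter()
        preds = ensemble.predict_gbm(model, test, feature_names)
        t2 = time.perf_counter()
        return preds, t1 - t0, t2 - t1
    fusion, base_kind = method.split("-")
    t0 = time.perf_counter()
    bank = ensemble.train_base_bank(train, base_kind, feature_names, seed)
    weights = None
    if fusion == "wv":
        weights = ensemble.derive_weight_matrix(
            train, base_kind, feature_names, k_inner=5, seed=seed
        )
    t1 = time.perf_counter()
    base_labels = bank.predict_labels(test)
    preds = ensemble.fuse_predictions(base_labels, rng, weights)
    t2 = time.perf_counter()
    return preds, t1 - t0, t2 - t1


def evaluate_method(
    features: pd.DataFrame,
    method: str,
    k: int = 5,
    seed: int = 0,
    feature_names: tuple[str, ...] = SELECTED_FEATURES,
) -> EvalReport:
    """K-fold stratified cross-validation of one method.

    Held-out predictions are pooled across folds into a single confusion
    matrix (every window predicted exactly once); timing values are
    per-fold means.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    y = features["label"].to_numpy()
    plan = stratified_folds(y, k=k, seed=seed)
    rng = np.random.default_rng(seed + 1)  # tie-break substream
    preds = np.zeros_like(y)
    t_train, t_pred = [], []
    for fold in range(k):
        test_mask = plan.assignments == fold
        train_df = features.loc[~test_mask].reset_index(drop=True)
        test_df = features.loc[test_mask].reset_index(drop=True)
        p, tt, tp = _fit_predict(method, train_df, test_df, feature_names, seed, rng)
        preds[test_mask] = p
        t_train.append(tt)
        t_pred.append(tp)
    cm = confusion_matrix(y, preds)
    true_counts = cm.sum(axis=1)
    with np.errstate(invalid="ignore"):
        per_class = np.where(true_counts > 0, np.diag(cm) / np.maximum(true_counts, 1), np.nan)
    return EvalReport(
        method=method,
        confusion=cm,
        per_class_accuracy=per_class,
        overall_accuracy=float(np.trace(cm) / cm.sum()),
        macro_f1=macro_f1(cm),
        t_train=float(np.mean(t_train)),
        t_predict=float(np.mean(t_pred)),
        seed=seed,
    )


def evaluate_all(
    features: pd.DataFrame,
    methods: tuple[str, ...] = METHODS,
    k: int = 5,
    seed: int = 0,
    feature_names: tuple[str, ...] = SELECTED_FEATURES,
) -> dict[str, EvalReport]:
    return {
        m: evaluate_method(features, m, k=k, seed=seed, feature_names=feature_names)
        for m in methods
    }


def report_tables(reports: dict[str, EvalReport]) -> dict[str, pd.DataFrame]:
    """Human-readable summary tables.

    ``per_class``: per-class recall per method with an Overall row;
    ``summary``: overall accuracy and macro-F1 per method; ``timing``:
    mean per-fold train/predict wall-clock seconds.
    """
    from .preprocess import label_to_terrain_kind

    if not reports:
        raise ValueError("no reports supplied")
    methods = list(reports)
    rows = []
    for lab in range(1, 13):
        terrain, kind = label_to_terrain_kind(lab)
        row: dict = {"terrain": terrain, "phase": kind}
        for m in methods:
            row[m] = reports[m].per_class_accuracy[lab - 1]
        rows.append(row)
    overall: dict = {"terrain": "Overall", "phase": ""}
    for m in methods:
        overall[m] = reports[m].overall_accuracy
    rows.append(overall)
    per_class = pd.DataFrame(rows)

    summary = pd.DataFrame(
        {
            "method": methods,
            "overall_accuracy": [reports[m].overall_accuracy for m in methods],
            "macro_f1": [reports[m].macro_f1 for m in methods],
        }
    )
    timing = pd.DataFrame(
        {
            "method": methods,
            "t_train": [reports[m].t_train for m in methods],
            "t_predict": [reports[m].t_predict for m in methods],
        }
    )
    return {"per_class": per_class, "summary": summary, "timing": timing}
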