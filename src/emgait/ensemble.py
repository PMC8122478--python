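"""Classifier fusion and gradient boosting for 12-class locomotion modes.

Six base classifiers (LDA or RBF-SVM) are trained, one per selected
feature, each seeing only that feature's five channel values. Their hard
labels are fused either by plurality voting (ties broken uniformly at
random) or by weighted majority voting: classifier j contributes weight
W[j, c] to class c when it votes c, where W is a (6, 12) matrix of
per-class confidences estimated by nested stratified cross-training —
within the training partition, each base classifier's held-out
predictions are pooled and W[j, c] is its recall on class c. The
comparator is a multiclass LightGBM model trained on the concatenated
30-column feature matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import SELECTED_FEATURES, select_feature_block

N_CLASSES = 12


def _make_base(base_kind: str, seed: int):
    if base_kind == "lda":
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    if base_kind == "svm":
        return SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed)
    raise ValueError(f"unknown base classifier kind {base_kind!r}")


@dataclass
class BaseClassifierBank:
    """One trained model per selected feature (each on its 5-channel block)."""

    base_kind: str
    classifiers: list
    feature_names: tuple[str, ...]

    def predict_labels(self, df: pd.DataFrame) -> np.ndarray:
        """(n_windows, N) matrix of base-classifier hard labels."""
        preds = [
            clf.predict(select_feature_block(df, feat))
            for clf, feat in zip(self.classifiers, self.feature_names)
        ]
        return np.column_stack(preds)


def train_base_bank(
    train: pd.DataFrame,
    base_kind: str = "svm",
    feature_names: tuple[str, ...] = SELECTED_FEATURES,
    seed: int = 0,
) -> BaseClassifierBank:
    """Fit the N single-feature base classifiers on a training matrix."""
    y = train["label"].to_numpy()
    if np.unique(y).size < 2:
        raise ValueError("training data must contain more than one class")
    classifiers = []
    for feat in feature_names:
        x = select_feature_block(train, feat)
        clf = _make_base(base_kind, seed)
        clf.fit(x, y)
        classifiers.append(clf)
    return BaseClassifierBank(base_kind, classifiers, tuple(feature_names))


def plurality_vote(base_labels: np.ndarray, rng: np.random.Generator) -> int:
    """Label with the most votes; ties resolved uniformly at random."""
    base_labels = np.asarray(base_labels)
    if base_labels.size == 0:
        raise ValueError("no base labels supplied")
    labels, counts = np.unique(base_labels, return_counts=True)
    tied = labels[counts == counts.max()]
    if tied.size == 1:
        return int(tied[0])
    return int(rng.choice(tied))


def weighted_vote(
    base_labels: np.ndarray, weights: np.ndarray, rng: np.random.Generator
) -> int:
    """argmax_c sum_j W[j, c] * 1[d_j = c]; random uniform tie-break."""
    base_labels = np.asarray(base_labels)
    weights = np.asarray(weights, dtype=float)
    if weights.ndim != 2 or base_labels.shape[0] != weights.shape[0]:
        raise ValueError("weight matrix shape does not match the label count")
    scores = np.zeros(weights.shape[1])
    for j, lab in enumerate(base_labels):
        scores[lab - 1] += weights[j, lab - 1]
    best = np.flatnonzero(scores == scores.max())
    if best.size == 1:
        return int(best[0]) + 1
    return int(rng.choice(best)) + 1


def recall_matrix(y_true: np.ndarray, preds: np.ndarray, n_classes: int = N_CLASSES) -> np.ndarray:
    """Per-classifier, per-class recall.

    ``preds`` has shape (n_classifiers, n_samples); the result is the
    (n_classifiers, n_classes) matrix of class-conditional accuracies.
    """
    y_true = np.asarray(y_true)
    preds = np.atleast_2d(np.asarray(preds))
    if preds.shape[1] != y_true.shape[0]:
        raise ValueError("preds must have shape (n_classifiers, n_samples)")
    w = np.zeros((preds.shape[0], n_classes))
    for c in range(1, n_classes + 1):
        mask = y_true == c
        n_c = int(mask.sum())
        if n_c == 0:
            continue
        w[:, c - 1] = (preds[:, mask] == c).sum(axis=1) / n_c
    return w


def derive_weight_matrix(
    train: pd.DataFrame,
    base_kind: str = "svm",
    feature_names: tuple[str, ...] = SELECTED_FEATURES,
    k_inner: int = 5,
    seed: int = 0,
    n_classes: int = N_CLASSES,
    bank_factory=None,
) -> np.ndarray:
    """Estimate the (N, L) confidence matrix by nested cross-training.

    The training partition is split into ``k_inner`` stratified folds;
    each base classifier is refitted on the inner-train part and its
    predictions on the inner-held-out part are pooled over folds, giving
    one out-of-sample prediction per training window. W[j, c] is then
    classifier j's recall on class c over those pooled predictions.

    ``bank_factory(train, base_kind, feature_names, seed)`` defaults to
    :func:`train_base_bank`; injectable so designed classifier banks with
    known error structure can be used to validate the estimator.
    """
    if bank_factory is None:
        bank_factory = train_base_bank
    y = train["label"].to_numpy()
    counts = pd.Series(y).value_counts()
    if counts.min() < k_inner:
        raise ValueError(
            f"smallest class has {counts.min()} members; use k_inner <= that"
        )
    skf = StratifiedKFold(n_splits=k_inner, shuffle=True, random_state=seed)
    n = len(train)
    pooled = np.zeros((len(feature_names), n), dtype=int)
    for tr_idx, ho_idx in skf.split(np.zeros(n), y):
        inner = train.iloc[tr_idx]
        bank = bank_factory(inner, base_kind, feature_names, seed)
        preds = bank.predict_labels(train.iloc[ho_idx])  # (n_ho, N)
        pooled[:, ho_idx] = preds.T
    return recall_matrix(y, pooled, n_classes)


def fuse_predictions(
    base_label_matrix: np.ndarray,
    rng: np.random.Generator,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Fuse an (n_windows, N) base-label matrix window by window."""
    base_label_matrix = np.atleast_2d(np.asarray(base_label_matrix))
    out = np.empty(base_label_matrix.shape[0], dtype=int)
    for i, row in enumerate(base_label_matrix):
        if weights is None:
            out[i] = plurality_vote(row, rng)
        else:
            out[i] = weighted_vote(row, weights, rng)
    return out


def train_gbm(
    train: pd.DataFrame,
    feature_names: tuple[str, ...] = SELECTED_FEATURES,
    seed: int = 0,
    n_estimators: int = 200,
    num_leaves: int = 31,
    learning_rate: float = 0.1,
) -> LGBMClassifier:
    """Multiclass boosted-tree model on the concatenated feature block."""
    y = train["label"].to_numpy()
    if np.unique(y).size < 2:
        raise ValueError("training data must contain more than one class")
    x = _gbm_design(train, feature_names)
    model = LGBMClassifier(
        n_estimators=n_estimators,
        num_leaves=num_leaves,
        learning_rate=learning_rate,
        random_state=seed,
        n_jobs=1,
        deterministic=True,
        force_row_wise=True,
        verbose=-1,
    )
    model.fit(x, y)
    return model


def _gbm_design(df: pd.DataFrame, feature_names: tuple[str, ...]) -> pd.DataFrame:
    blocks = [select_feature_block(df, f) for f in feature_names]
    x = np.hstack(blocks)
    cols = [f"f{i}" for i in range(x.shape[1])]
    return pd.DataFrame(x, columns=cols)


def predict_gbm(
    model: LGBMClassifier, df: pd.DataFrame, feature_names: tuple[str, ...] = SELECTED_FEATURES
) -> np.ndarray:
    return np.asarray(model.predict(_gbm_design(df, feature_names)), dtype=int)
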