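"""Separability-based feature selection.

Each candidate feature is judged on how well its 5-channel value vector
separates the 12 locomotion classes, using three statistical criteria
(lower is better in all three, after inverting RES):

* Davies-Bouldin index: DB = (1/L) sum_i max_{j!=i} (D_ii+D_jj)/D_ij,
  where D_ii is the mean Euclidean distance of class-i members to their
  centroid and D_ij the distance between class centroids.
* Scattering index: J = trace(S_W)/trace(S_B) with S_W the pooled
  (class-size-weighted) within-class covariance and S_B the
  between-class covariance of class means about the grand mean.
* RES, the mean over ordered class pairs of the ratio of centroid
  distance to the average within-class standard deviation; its inverse
  invRES is reported so that lower is uniformly better.

Robustness is the across-subject sample standard deviation of each
index (STN); features are ranked by mean invRES (ascending) with STN as
the tie-breaker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import ALL_FEATURES, SELECTED_FEATURES, select_feature_block

logger = logging.getLogger(__name__)

INF = float("inf")


@dataclass
class ClassCloud:
    """Per-class summary of one feature's 5-channel vectors."""

    label: int
    mean: np.ndarray          # centroid, shape (d,)
    dispersion: float         # mean Euclidean distance of members to centroid
    std: float                # scalar spread: sqrt(mean per-dimension variance)
    cov: np.ndarray           # (d, d) covariance, ddof=0
    count: int


def class_clouds(values: np.ndarray, labels: np.ndarray) -> list[ClassCloud]:
    """Summarize (n, d) feature vectors into per-class clouds."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    clouds = []
    for lab in np.unique(labels):
        pts = values[labels == lab]
        if pts.shape[0] < 2:
            raise ValueError(f"class {lab} has fewer than 2 members")
        mu = pts.mean(axis=0)
        disp = float(np.mean(np.linalg.norm(pts - mu, axis=1)))
        var_per_dim = pts.var(axis=0, ddof=0)
        clouds.append(
            ClassCloud(
                label=int(lab),
                mean=mu,
                dispersion=disp,
                std=float(np.sqrt(np.mean(var_per_dim))),
                cov=np.cov(pts, rowvar=False, ddof=0).reshape(pts.shape[1], pts.shape[1]),
                count=pts.shape[0],
            )
        )
    return clouds


def db_index(clouds: list[ClassCloud]) -> float:
    """Davies-Bouldin index; +inf when coincident centroids have spread."""
    L = len(clouds)
    total = 0.0
    for i in range(L):
        worst = 0.0
        for j in range(L):
            if i == j:
                continue
            d_ij = float(np.linalg.norm(clouds[i].mean - clouds[j].mean))
            num = clouds[i].dispersion + clouds[j].dispersion
            if d_ij == 0.0:
                if num > 0.0:
                    logger.warning("db_index: coincident class means with spread")
                    return INF
                ratio = 0.0
            else:
                ratio = num / d_ij
            worst = max(worst, ratio)
        total += worst
    return total / L


def scattering_index(values: np.ndarray, labels: np.ndarray) -> float:
    """J = trace(S_W)/trace(S_B), class-size-weighted covariances."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    n = values.shape[0]
    grand = values.mean(axis=0)
    sw = np.zeros((values.shape[1], values.shape[1]))
    sb = np.zeros_like(sw)
    for lab in np.unique(labels):
        pts = values[labels == lab]
        w = pts.shape[0] / n
        mu = pts.mean(axis=0)
        centered = pts - mu
        sw += w * (centered.T @ centered) / pts.shape[0]
        diff = (mu - grand)[:, None]
        sb += w * (diff @ diff.T)
    tr_b = float(np.trace(sb))
    if tr_b == 0.0:
        return INF
    return float(np.trace(sw)) / tr_b


def res_index(clouds: list[ClassCloud]) -> tuple[float, float]:
    """(RES, invRES): mean ordered-pair centroid distance over mean spread."""
    L = len(clouds)
    total = 0.0
    used = 0
    for i in range(L):
        for j in range(L):
            if i == j:
                continue
            denom = 0.5 * (clouds[i].std + clouds[j].std)
            if denom == 0.0:
                logger.warning("res_index: pair (%d, %d) has zero spread; skipped",
                               clouds[i].label, clouds[j].label)
                continue
            d_ij = float(np.linalg.norm(clouds[i].mean - clouds[j].mean))
            total += d_ij / denom
            used += 1
    if used == 0:
        return INF, 0.0
    res = total / used
    inv = 1.0 / res if res > 0 else INF
    return res, inv


def stn(index_values) -> float:
    """Across-subject robustness: sample standard deviation (ddof=1)."""
    vals = np.asarray(index_values, dtype=float)
    if vals.size < 2:
        raise ValueError("STN needs at least 2 subjects")
    return float(np.sqrt(np.sum((vals - vals.mean()) ** 2) / (vals.size - 1)))


def feature_indices(df: pd.DataFrame, feature_name: str) -> dict[str, float]:
    """DB, J, RES and invRES of one feature in one subject's matrix."""
    values = select_feature_block(df, feature_name)
    labels = df["label"].to_numpy()
    clouds = class_clouds(values, labels)
    res, inv = res_index(clouds)
    return {
        "DB": db_index(clouds),
        "J": scattering_index(values, labels),
        "RES": res,
        "invRES": inv,
    }


def rank_features(
    subject_matrices: list[pd.DataFrame],
    features: tuple[str, ...] = ALL_FEATURES,
    top_k: int = 6,
) -> pd.DataFrame:
    """Separability report across subjects, ranked by mean invRES.

    Returns one row per feature with per-index means and STN values, a
    ``rank`` column (1 = best, mean invRES ascending, STN_invRES
    tie-break) and a boolean ``selected`` column marking the top-k set.
    """
    if len(subject_matrices) < 2:
        raise ValueError("need >= 2 subjects to compute STN")
    expected = set(range(1, 13))
    for si, df in enumerate(subject_matrices):
        present = set(int(v) for v in df["label"].unique())
        missing = expected - present
        if missing:
            raise ValueError(f"subject index {si} is missing classes {sorted(missing)}")

    records = []
    for feat in features:
        per_subject = [feature_indices(df, feat) for df in subject_matrices]
        rec = {"feature": feat}
        for key in ("DB", "J", "invRES"):
            vals = [p[key] for p in per_subject]
            rec[f"{key}_mean"] = float(np.mean(vals))
            rec[f"STN_{key}"] = stn(vals) if np.all(np.isfinite(vals)) else INF
        records.append(rec)
    report = pd.DataFrame(records)
    report = report.sort_values(
        ["invRES_mean", "STN_invRES", "feature"], kind="mergesort"
    ).reset_index(drop=True)
    report["rank"] = np.arange(1, len(report) + 1)
    report["selected"] = report["rank"] <= top_k
    return report


def selected_set(report: pd.DataFrame, use_reference_set: bool = False) -> tuple[str, ...]:
    """The classifier input features: ranked top-k, or the pinned six-
    feature reference set (MAV, WL, RMS, Db1-cD2-MAV, Db1-cD1-WL,
    Db1-cD2-WL) when ``use_reference_set`` is given."""
    if use_reference_set:
        return SELECTED_FEATURES
    return tuple(report.loc[report["selected"], "feature"])
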