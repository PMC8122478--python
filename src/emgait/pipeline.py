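"""End-to-end convenience driver: simulation through evaluation."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import synth
from .evaluation import METHODS, EvalReport, evaluate_all
from .features import FeatureSpec, SELECTED_FEATURES, build_feature_matrix
from .preprocess import preprocess_recording


def subject_feature_matrix(
    config: synth.SimulationConfig,
    subject_id: str = "S1",
    spec: FeatureSpec | None = None,
    selected: tuple[str, ...] | None = None,
    denoise: bool = True,
) -> pd.DataFrame:
    """Simulate one subject's session and produce its labeled feature matrix."""
    session = synth.generate_session(config)
    windows = []
    for terrain in synth.TERRAINS:
        rec, pres, _truth = session[terrain]
        _, _, w = preprocess_recording(rec, pres, denoise=denoise)
        windows.extend(w)
    return build_feature_matrix(windows, spec=spec, selected=selected, subject_id=subject_id)


def cohort_feature_matrices(
    n_subjects: int = 3,
    base_config: synth.SimulationConfig | None = None,
    seed: int = 0,
    selected: tuple[str, ...] | None = None,
    denoise: bool = True,
) -> list[pd.DataFrame]:
    """Feature matrices for a cohort of virtual subjects."""
    configs = synth.virtual_subjects(n_subjects, base_config, seed=seed)
    return [
        subject_feature_matrix(cfg, subject_id=f"S{si + 1}", selected=selected, denoise=denoise)
        for si, cfg in enumerate(configs)
    ]


def evaluate_cohort(
    matrices: list[pd.DataFrame],
    methods: tuple[str, ...] = METHODS,
    k: int = 5,
    seed: int = 0,
    feature_names: tuple[str, ...] = SELECTED_FEATURES,
) -> dict[str, dict[str, EvalReport]]:
    """Within-subject evaluation of each method for every subject."""
    out: dict[str, dict[str, EvalReport]] = {}
    for df in matrices:
        subject = str(df["subject"].iloc[0])
        out[subject] = evaluate_all(df, methods, k=k, seed=seed, feature_names=feature_names)
    return out


def cohort_summary(reports: dict[str, dict[str, EvalReport]]) -> pd.DataFrame:
    """Per-subject and average overall accuracy / macro-F1 per method."""
    subjects = list(reports)
    methods = list(next(iter(reports.values())))
    rows = []
    for s in subjects:
        for m in methods:
            r = reports[s][m]
            rows.append(
                {
                    "subject": s,
                    "method": m,
                    "overall_accuracy": r.overall_accuracy,
                    "macro_f1": r.macro_f1,
                }
            )
    df = pd.DataFrame(rows)
    avg = (
        df.groupby("method", sort=False)[["overall_accuracy", "macro_f1"]]
        .mean()
        .reset_index()
        .assign(subject="Average")
    )
    return pd.concat([df, avg[df.columns]], ignore_index=True)
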