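"""Published reference results of the four-participant gait study that
this pipeline models.

The study evaluated five ensemble methods (plurality and weighted
majority voting over LDA or SVM base classifiers, and LightGBM) on
12-class gait-phase-by-terrain recognition, within subject, with
stratified 5-fold cross-validation. The per-subject overall accuracies
and macro-F1 scores reported there are kept here as reference data so
the pipeline's summary arithmetic (cross-subject averaging, printed
precision) can be checked against them. They are NOT produced by this
package and subject-level values cannot be reproduced (the recordings
were never deposited).
"""

from __future__ import annotations

import numpy as np

METHODS = ("mv-lda", "mv-svm", "wv-lda", "wv-svm", "lgbm")
SUBJECTS = ("S1", "S2", "S3", "S4")

#: Per-subject overall classification accuracy (percent) per method.
OVERALL_ACCURACY_PCT: dict[str, dict[str, float]] = {
    "S1": {"mv-lda": 89.77, "mv-svm": 92.27, "wv-lda": 89.77, "wv-svm": 92.27, "lgbm": 92.73},
    "S2": {"mv-lda": 87.41, "mv-svm": 88.70, "wv-lda": 87.04, "wv-svm": 88.70, "lgbm": 92.96},
    "S3": {"mv-lda": 86.16, "mv-svm": 89.05, "wv-lda": 85.33, "wv-svm": 89.26, "lgbm": 93.80},
    "S4": {"mv-lda": 81.10, "mv-svm": 84.45, "wv-lda": 80.12, "wv-svm": 83.86, "lgbm": 92.73},
}

#: Per-subject macro-F1 score per method, and the reported Average row.
MACRO_F1: dict[str, dict[str, float]] = {
    "S1": {"mv-lda": 0.896, "mv-svm": 0.923, "wv-lda": 0.896, "wv-svm": 0.923, "lgbm": 0.928},
    "S2": {"mv-lda": 0.867, "mv-svm": 0.867, "wv-lda": 0.860, "wv-svm": 0.867, "lgbm": 0.918},
    "S3": {"mv-lda": 0.869, "mv-svm": 0.892, "wv-lda": 0.858, "wv-svm": 0.895, "lgbm": 0.940},
    "S4": {"mv-lda": 0.818, "mv-svm": 0.849, "wv-lda": 0.807, "wv-svm": 0.844, "lgbm": 0.928},
}

REPORTED_MACRO_F1_AVERAGE: dict[str, float] = {
    "mv-lda": 0.863, "mv-svm": 0.883, "wv-lda": 0.855, "wv-svm": 0.882, "lgbm": 0.929,
}

#: Headline reported figure: cross-subject average LightGBM accuracy.
REPORTED_AVERAGE_LGBM_ACCURACY_PCT = 93.1


def mean_overall_accuracy_pct(method: str) -> float:
    """Cross-subject mean of the reference overall accuracies (percent)."""
    return float(np.mean([OVERALL_ACCURACY_PCT[s][method] for s in SUBJECTS]))


def mean_macro_f1(method: str) -> float:
    """Cross-subject mean of the reference macro-F1 scores."""
    return float(np.mean([MACRO_F1[s][method] for s in SUBJECTS]))
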