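"""The 35 per-channel sEMG features: time, frequency, and wavelet domain.

Time domain (12): MAV, WAMP, ZC, WL, SSC, LogVAR, RMS, Q3 and the four
coefficients of an order-4 autoregressive fit (AR1..AR4, Yule-Walker
with biased autocovariance, prediction convention
x_t = sum_k a_k x_{t-k} + e_t).

Frequency domain (5), from a Hann-tapered periodogram of the 100-sample
window (5 Hz bins at 500 Hz): median frequency MDF, mean frequency MNF,
low/high band power ratio PR (split at 75 Hz by default), peak frequency
PKF, mean power MNP.

Time-frequency (18): 3-level discrete wavelet decomposition with db1,
db4 and db7; the two finest detail bands cD1 and cD2 are kept (cA3/cD3
carry low-resolution background and are discarded) and MAV, WAMP and WL
are computed on each coefficient array — 3 bases x 2 bands x 3 stats.

Feature values are assembled into a windows x (channel, feature) matrix
with 12-class (terrain x window-kind) labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps
from statsmodels.regression.linear_model import yule_walker

from .preprocess import AnalysisWindow
from .synth import MUSCLES

TIME_DOMAIN_FEATURES = (
    "MAV", "WAMP", "ZC", "WL", "SSC", "LogVAR", "RMS", "Q3",
    "AR1", "AR2", "AR3", "AR4",
)
FREQ_DOMAIN_FEATURES = ("MDF", "MNF", "PR", "PKF", "MNP")
WAVELET_BASES = ("db1", "db4", "db7")
WAVELET_SUBBANDS = ("cD1", "cD2")
WAVELET_STATS = ("MAV", "WAMP", "WL")
WAVELET_FEATURES = tuple(
    f"Db{b[2:]}-{sb}-{st}"
    for b in WAVELET_BASES
    for sb in WAVELET_SUBBANDS
    for st in WAVELET_STATS
)
ALL_FEATURES = TIME_DOMAIN_FEATURES + FREQ_DOMAIN_FEATURES + WAVELET_FEATURES

#: The six-feature set with the best separability/robustness trade-off,
#: used as the default classifier input.
SELECTED_FEATURES = ("MAV", "WL", "RMS", "Db1-cD2-MAV", "Db1-cD1-WL", "Db1-cD2-WL")


@dataclass
class FeatureSpec:
    """Tunable feature parameters.

    ``wamp_threshold`` of None means 5% of the per-channel RMS over the
    training windows (amplitude-robust default); ZC/SSC thresholds
    default to 0. ``pr_split`` is the PR band boundary in Hz (midpoint of
    the 10-150 Hz passband). ``logvar_epsilon`` keeps LogVAR finite on
    degenerate windows.
    """

    wamp_threshold: float | None = None
    zc_threshold: float = 0.0
    ssc_threshold: float = 0.0
    pr_split: float = 75.0
    logvar_epsilon: float = 1e-12
    ar_order: int = 4
    wavelet_level: int = 3
    dwt_mode: str = "symmetric"

    def resolved_wamp(self, channel_rms: float) -> float:
        if self.wamp_threshold is not None:
            return self.wamp_threshold
        return 0.05 * channel_rms


def _mav(x: np.ndarray) -> float:
    return float(np.mean(np.abs(x)))


def _wamp(x: np.ndarray, thr: float) -> float:
    return float(np.sum(np.abs(np.diff(x)) > thr))


def _zc(x: np.ndarray, thr: float) -> float:
    sign_change = x[:-1] * x[1:] < 0
    big_enough = np.abs(x[:-1] - x[1:]) >= thr
    return float(np.sum(sign_change & big_enough))


def _wl(x: np.ndarray) -> float:
    return float(np.sum(np.abs(np.diff(x))))


def _ssc(x: np.ndarray, thr: float) -> float:
    d1 = x[1:-1] - x[:-2]
    d2 = x[1:-1] - x[2:]
    return float(np.sum(d1 * d2 > thr))


def _ar_coefficients(x: np.ndarray, order: int) -> np.ndarray:
    """Order-``order`` Yule-Walker AR fit; zeros for (near-)constant input."""
    if np.var(x) < 1e-24:
        return np.zeros(order)
    rho, _ = yule_walker(x, order=order, method="mle")  # biased autocovariance
    return np.asarray(rho, dtype=float)


def time_domain_features(x: np.ndarray, spec: FeatureSpec, channel_rms: float | None = None) -> dict[str, float]:
    """The 12 time-domain features of one window."""
    x = np.asarray(x, dtype=float)
    rms = float(np.sqrt(np.mean(x**2)))
    thr_w = spec.resolved_wamp(channel_rms if channel_rms is not None else rms)
    ar = _ar_coefficients(x, spec.ar_order)
    vals = {
        "MAV": _mav(x),
        "WAMP": _wamp(x, thr_w),
        "ZC": _zc(x, spec.zc_threshold),
        "WL": _wl(x),
        "SSC": _ssc(x, spec.ssc_threshold),
        "LogVAR": float(np.log(np.var(x) + spec.logvar_epsilon)),
        "RMS": rms,
        "Q3": float(np.percentile(x, 75)),
    }
    for k in range(spec.ar_order):
        vals[f"AR{k + 1}"] = float(ar[k])
    return vals


def power_spectrum(x: np.ndarray, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Hann-tapered periodogram (frequencies, power density)."""
    f, p = sps.periodogram(x, fs=rate, window="hann", detrend=False)
    return f, p


def frequency_domain_features(x: np.ndarray, rate: float, spec: FeatureSpec) -> dict[str, float]:
    """MDF, MNF, PR, PKF, MNP from the window's periodogram."""
    x = np.asarray(x, dtype=float)
    f, p = power_spectrum(x, rate)
    total = float(np.sum(p))
    if total <= 0:
        return {"MDF": 0.0, "MNF": 0.0, "PR": 0.0, "PKF": 0.0, "MNP": 0.0}
    cum = np.cumsum(p)
    mdf = float(f[np.searchsorted(cum, 0.5 * total)])
    mnf = float(np.sum(f * p) / total)
    pkf = float(f[int(np.argmax(p))])
    mnp = float(np.mean(p))
    low = float(np.sum(p[f < spec.pr_split]))
    high = float(np.sum(p[f >= spec.pr_split]))
    pr = float(low / high) if high > 0 else 0.0
    return {"MDF": mdf, "MNF": mnf, "PR": pr, "PKF": pkf, "MNP": mnp}


def dwt_details(x: np.ndarray, wavelet: str, level: int = 3, mode: str = "symmetric") -> dict[str, np.ndarray]:
    """Detail coefficient arrays cD1..cD<level> of a ``level``-deep DWT."""
    x = np.asarray(x, dtype=float)
    # longer filters (db7) support fewer clean levels on 100-sample
    # windows; the finest details cD1/cD2 are identical either way
    max_level = pywt.dwt_max_level(x.size, pywt.Wavelet(wavelet).dec_len)
    level = max(min(level, max_level), min(2, level))
    coeffs = pywt.wavedec(x, wavelet, level=level, mode=mode)
    # wavedec returns [cA_L, cD_L, ..., cD_1]
    return {f"cD{k}": coeffs[-k] for k in range(1, level + 1)}


def wavelet_features(x: np.ndarray, spec: FeatureSpec, channel_rms: float | None = None) -> dict[str, float]:
    """18 DWT features: {db1,db4,db7} x {cD1,cD2} x {MAV,WAMP,WL}."""
    x = np.asarray(x, dtype=float)
    rms = float(np.sqrt(np.mean(x**2)))
    thr_w = spec.resolved_wamp(channel_rms if channel_rms is not None else rms)
    out: dict[str, float] = {}
    for basis in WAVELET_BASES:
        details = dwt_details(x, basis, level=spec.wavelet_level, mode=spec.dwt_mode)
        for sb in WAVELET_SUBBANDS:
            c = details[sb]
            prefix = f"Db{basis[2:]}-{sb}"
            out[f"{prefix}-MAV"] = _mav(c)
            out[f"{prefix}-WAMP"] = _wamp(c, thr_w)
            out[f"{prefix}-WL"] = _wl(c)
    return out


def window_features(
    samples: np.ndarray,
    rate: float,
    spec: FeatureSpec,
    channel_rms: np.ndarray | None = None,
    muscle_names: tuple[str, ...] = MUSCLES,
) -> dict[str, float]:
    """All 35 features for every channel of one window, keyed muscle_feature."""
    samples = np.asarray(samples, dtype=float)
    out: dict[str, float] = {}
    for ci, muscle in enumerate(muscle_names):
        x = samples[ci]
        crms = None if channel_rms is None else float(channel_rms[ci])
        vals = time_domain_features(x, spec, crms)
        vals.update(frequency_domain_features(x, rate, spec))
        vals.update(wavelet_features(x, spec, crms))
        for name, v in vals.items():
            out[f"{muscle}_{name}"] = v
    return out


def build_feature_matrix(
    windows: list[AnalysisWindow],
    spec: FeatureSpec | None = None,
    selected: tuple[str, ...] | None = None,
    subject_id: str = "S1",
    rate: float = 500.0,
) -> pd.DataFrame:
    """Assemble the labeled feature matrix from analysis windows.

    Full spec gives 5 channels x 35 features = 175 feature columns;
    restricting to the default six-feature set gives 30. Row order
    follows window order. The WAMP threshold, when unset, is resolved to
    5% of each channel's RMS pooled over all supplied windows.
    """
    if not windows:
        raise ValueError("no windows supplied")
    spec = spec or FeatureSpec()
    n_samp = {w.samples.shape[1] for w in windows}
    if len(n_samp) != 1:
        raise ValueError(f"windows have mixed sample counts: {sorted(n_samp)}")
    stacked = np.stack([w.samples for w in windows])  # (n, channels, t)
    channel_rms = np.sqrt(np.mean(stacked**2, axis=(0, 2)))

    feature_names = ALL_FEATURES if selected is None else selected
    unknown = set(feature_names) - set(ALL_FEATURES)
    if unknown:
        raise ValueError(f"unknown feature(s): {sorted(unknown)}")

    muscle_names = windows[0].samples.shape[0] == len(MUSCLES) and MUSCLES or tuple(
        f"ch{i + 1}" for i in range(windows[0].samples.shape[0])
    )
    rows = []
    for w in windows:
        feats = window_features(w.samples, rate, spec, channel_rms, muscle_names)
        row = {
            "subject": subject_id,
            "terrain": w.terrain,
            "kind": w.kind,
            "label": w.class_label,
        }
        for m in muscle_names:
            for fname in feature_names:
                row[f"{m}_{fname}"] = feats[f"{m}_{fname}"]
        rows.append(row)
    df = pd.DataFrame(rows)
    if df[feature_columns(df)].isna().any().any():
        raise ValueError("feature matrix contains missing values")
    return df


def feature_columns(df: pd.DataFrame) -> list[str]:
    """The feature columns of a matrix (everything beyond the metadata)."""
    meta = {"subject", "terrain", "kind", "label"}
    return [c for c in df.columns if c not in meta]


def select_feature_block(df: pd.DataFrame, feature_name: str) -> np.ndarray:
    """The (n_windows, 5) block of one feature across all channels."""
    cols = [c for c in feature_columns(df) if c.split("_", 1)[1] == feature_name]
    if not cols:
        raise KeyError(f"feature {feature_name!r} not present")
    return df[cols].to_numpy(dtype=float)
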