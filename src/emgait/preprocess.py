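"""Signal conditioning, gait-event extraction, cycle segmentation, windowing.

The conditioning chain mirrors standard gait-sEMG practice: resample to
500 Hz, band-pass 10–150 Hz, notch out 50 Hz powerline and its in-band
harmonics (100, 150 Hz), then wavelet-denoise to suppress residual
motion artifact. All filtering is zero-phase (forward-backward) so that
event-aligned analysis windows stay aligned.

Gait events are read off the foot-pressure insole channels: heel strike
(HS) from rising heel loading, toe off (TO) from the toe channel
unloading, with hysteresis thresholds. A gait cycle spans consecutive
HS events; four 200-ms analysis windows are anchored to HS and TO
(Post_HC, Pre_TO, Post_TO, Pre_HC), and each window carries a class
label in 1..12 combining terrain and window kind.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pywt
from scipy import signal as sps

from .synth import EmgRecording, PressureTrace, TERRAINS

logger = logging.getLogger(__name__)

TARGET_RATE = 500.0
WINDOW_DURATION = 0.200
WINDOW_KINDS = ("Post_HC", "Pre_TO", "Post_TO", "Pre_HC")


@dataclass
class GaitEventSeries:
    """Heel-strike and toe-off times in seconds, strictly increasing."""

    hs_times: np.ndarray
    to_times: np.ndarray
    ts_times: np.ndarray | None = None
    ho_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.hs_times = np.asarray(self.hs_times, dtype=float)
        self.to_times = np.asarray(self.to_times, dtype=float)
        for arr in (self.hs_times, self.to_times):
            if arr.size > 1 and not np.all(np.diff(arr) > 0):
                raise ValueError("event times must be strictly increasing")


@dataclass
class GaitCycle:
    """One HS-to-HS cycle with its interior toe-off."""

    start_hs: float
    to: float
    end_hs: float
    terrain: str

    def __post_init__(self) -> None:
        if not self.start_hs < self.to < self.end_hs:
            raise ValueError("cycle requires start_hs < to < end_hs")


@dataclass
class AnalysisWindow:
    """A 200-ms, 100-sample (at 500 Hz) classification unit."""

    kind: str
    terrain: str
    start: float
    duration: float
    samples: np.ndarray  # (channels, 100)
    class_label: int


def class_label(terrain: str, kind: str) -> int:
    """Bijection of (terrain, window kind) onto 1..12."""
    return 4 * TERRAINS.index(terrain) + WINDOW_KINDS.index(kind) + 1


def label_to_terrain_kind(label: int) -> tuple[str, str]:
    if not 1 <= label <= 12:
        raise ValueError("label must lie in 1..12")
    q, r = divmod(label - 1, 4)
    return TERRAINS[q], WINDOW_KINDS[r]


def resample_signal(trace: np.ndarray, in_rate: float, out_rate: float) -> np.ndarray:
    """Anti-aliased resampling along the last axis.

    Output length is round(n * out_rate / in_rate). Equal rates pass the
    signal through unchanged.
    """
    if in_rate <= 0 or out_rate <= 0:
        raise ValueError("rates must be positive")
    trace = np.asarray(trace, dtype=float)
    n = trace.shape[-1]
    if n == 0:
        raise ValueError("cannot resample an empty trace")
    if in_rate == out_rate:
        return trace.copy()
    frac = Fraction(out_rate / in_rate).limit_denominator(10000)
    y = sps.resample_poly(trace, frac.numerator, frac.denominator, axis=-1)
    target = int(round(n * out_rate / in_rate))
    if y.shape[-1] > target:
        y = y[..., :target]
    elif y.shape[-1] < target:
        pad = [(0, 0)] * (y.ndim - 1) + [(0, target - y.shape[-1])]
        y = np.pad(y, pad, mode="edge")
    return y


def filter_emg(
    trace: np.ndarray,
    rate: float = TARGET_RATE,
    band: tuple[float, float] = (10.0, 150.0),
    notch_freqs: tuple[float, ...] = (50.0, 100.0, 150.0),
    notch_q: float = 30.0,
) -> np.ndarray:
    """Zero-phase 10–150 Hz band-pass plus notches at 50/100/150 Hz.

    4th-order Butterworth band-pass and IIR notches (Q=30), each applied
    forward-backward so the net phase is zero and event alignment is
    preserved.
    """
    trace = np.asarray(trace, dtype=float)
    sos = sps.butter(4, band, btype="bandpass", fs=rate, output="sos")
    min_len = 3 * (2 * sos.shape[0] + 1)
    if trace.shape[-1] < min_len:
        raise ValueError(f"trace too short to filter (need >= {min_len} samples)")
    y = sps.sosfiltfilt(sos, trace, axis=-1)
    for f0 in notch_freqs:
        if f0 >= rate / 2:
            continue
        b, a = sps.iirnotch(f0, notch_q, fs=rate)
        y = sps.filtfilt(b, a, y, axis=-1)
    return y


def denoise_wavelet(
    trace: np.ndarray,
    wavelet: str = "db4",
    level: int = 4,
    threshold_scale: float = 1.0,
    remove_baseline: bool = True,
) -> np.ndarray:
    """Wavelet suppression of motion artifact and broadband noise.

    A ``level``-deep db4 decomposition (orthonormal, periodized) splits
    the trace into a low-frequency approximation (0 to rate/2^(level+1),
    i.e. below ~15.6 Hz at 500 Hz) and detail bands. The approximation is
    taken as the motion-artifact estimate and subtracted; detail
    coefficients are soft-thresholded with the universal threshold
    sigma*sqrt(2*ln n), sigma estimated from the median absolute
    deviation of the finest detail band. Because the transform is
    orthonormal, output energy never exceeds input energy.
    """
    trace = np.asarray(trace, dtype=float)
    single = trace.ndim == 1
    x = np.atleast_2d(trace)
    out = np.empty_like(x)
    for i, row in enumerate(x):
        n = row.size
        max_level = pywt.dwt_max_level(n, pywt.Wavelet(wavelet).dec_len)
        lev = min(level, max_level)
        if lev < 1:
            out[i] = row
            continue
        coeffs = pywt.wavedec(row, wavelet, level=lev, mode="periodization")
        sigma = np.median(np.abs(coeffs[-1])) / 0.6745 if coeffs[-1].size else 0.0
        thr = threshold_scale * sigma * np.sqrt(2.0 * np.log(max(n, 2)))
        new = [np.zeros_like(coeffs[0]) if remove_baseline else coeffs[0]]
        for c in coeffs[1:]:
            new.append(np.sign(c) * np.maximum(np.abs(c) - thr, 0.0))
        rec = pywt.waverec(new, wavelet, mode="periodization")
        out[i] = rec[:n]
    return out[0] if single else out


def detect_gait_events(
    pressure: PressureTrace,
    rate: float | None = None,
    low_frac: float = 0.10,
    high_frac: float = 0.20,
) -> GaitEventSeries:
    """Extract HS/TO from heel/toe loading with hysteresis thresholds.

    HS is the heel channel's upward crossing of ``low_frac`` of its peak,
    validated by a subsequent excursion above ``high_frac`` (hysteresis
    rejects chatter); TO is the toe channel's downward crossing of
    ``low_frac`` after loading above ``high_frac``. The alternation
    constraint (exactly one TO per HS interval, the last one before the
    next HS) is enforced afterwards.
    """
    rate = pressure.rate if rate is None else rate
    heel, toe = pressure.heel, pressure.toe

    def onsets(x: np.ndarray) -> np.ndarray:
        peak = float(np.max(x)) if x.size else 0.0
        if peak <= 0:
            return np.array([])
        lo, hi = low_frac * peak, high_frac * peak
        times = []
        armed = True
        pending = None
        for i in range(1, x.size):
            if armed and x[i - 1] < lo <= x[i]:
                pending = i
                armed = False
            if pending is not None and x[i] >= hi:
                times.append(pending)
                pending = None
            if not armed and x[i] < lo and pending is None:
                armed = True
            if pending is not None and x[i] < lo:
                pending = None  # never reached hi: chatter
                armed = True
        return np.asarray(times) / rate

    def offsets(x: np.ndarray) -> np.ndarray:
        peak = float(np.max(x)) if x.size else 0.0
        if peak <= 0:
            return np.array([])
        lo, hi = low_frac * peak, high_frac * peak
        times = []
        loaded = False
        for i in range(1, x.size):
            if x[i] >= hi:
                loaded = True
            if loaded and x[i - 1] >= lo > x[i]:
                times.append(i)
                loaded = False
        return np.asarray(times) / rate

    hs = onsets(heel)
    to_all = offsets(toe)
    if hs.size == 0 and to_all.size == 0:
        logger.warning("no gait events found in pressure trace")
        return GaitEventSeries(np.array([]), np.array([]))

    # alternation: keep the last TO strictly inside each HS interval
    to_kept = []
    for k in range(hs.size - 1):
        inside = to_all[(to_all > hs[k]) & (to_all < hs[k + 1])]
        if inside.size:
            to_kept.append(inside[-1])
    # trailing TOs after the final HS are retained (belong to the open cycle)
    if hs.size:
        trailing = to_all[to_all > hs[-1]]
        if trailing.size:
            to_kept.append(trailing[-1])
    return GaitEventSeries(hs, np.asarray(to_kept))


def segment_cycles(events: GaitEventSeries, terrain: str) -> list[GaitCycle]:
    """One cycle per consecutive HS pair containing exactly one TO."""
    hs = events.hs_times
    if hs.size < 2:
        return []
    cycles = []
    dropped = 0
    for start, end in zip(hs[:-1], hs[1:]):
        inside = events.to_times[(events.to_times > start) & (events.to_times < end)]
        if inside.size == 1:
            cycles.append(GaitCycle(float(start), float(inside[0]), float(end), terrain))
        else:
            dropped += 1
    if dropped:
        logger.info("segment_cycles: dropped %d cycle(s) without a unique TO", dropped)
    return cycles


def extract_windows(
    recording: EmgRecording, cycle: GaitCycle
) -> list[AnalysisWindow]:
    """The four 200-ms event-anchored analysis windows of one cycle.

    Post_HC starts at the heel strike, Pre_TO ends at toe off, Post_TO
    starts at toe off, and Pre_HC ends at the next heel strike. Post_TO
    and Pre_HC may overlap in short swings; both are kept, drawn from the
    continuous recording. Windows that would start before the recording
    or run past its end are excluded.
    """
    if recording.rate != TARGET_RATE:
        raise ValueError("recording must be resampled to 500 Hz first")
    n_samp = int(round(WINDOW_DURATION * TARGET_RATE))
    n_total = recording.samples.shape[1]
    starts = {
        "Post_HC": cycle.start_hs,
        "Pre_TO": cycle.to - WINDOW_DURATION,
        "Post_TO": cycle.to,
        "Pre_HC": cycle.end_hs - WINDOW_DURATION,
    }
    windows = []
    for kind in WINDOW_KINDS:
        t0 = starts[kind]
        i0 = int(np.floor(t0 * TARGET_RATE))
        if t0 < cycle.start_hs - 1e-9 or i0 < 0 or i0 + n_samp > n_total:
            logger.info("extract_windows: %s window invalid for cycle at %.3f s",
                        kind, cycle.start_hs)
            continue
        # Pre_TO must not precede the cycle start (stance shorter than 200 ms)
        if kind == "Pre_TO" and t0 < cycle.start_hs - 1e-9:
            continue
        samples = recording.samples[:, i0 : i0 + n_samp]
        windows.append(
            AnalysisWindow(
                kind=kind,
                terrain=cycle.terrain,
                start=t0,
                duration=WINDOW_DURATION,
                samples=samples,
                class_label=class_label(cycle.terrain, kind),
            )
        )
    return windows


def preprocess_recording(
    recording: EmgRecording,
    pressure: PressureTrace,
    denoise: bool = True,
) -> tuple[EmgRecording, GaitEventSeries, list[AnalysisWindow]]:
    """Full conditioning chain for one terrain recording.

    Resamples EMG and pressure to 500 Hz, filters and denoises the EMG,
    detects gait events, segments cycles, and extracts the four analysis
    windows per cycle.
    """
    emg500 = resample_signal(recording.samples, recording.rate, TARGET_RATE)
    emg500 = filter_emg(emg500, TARGET_RATE)
    if denoise:
        emg500 = denoise_wavelet(emg500)
    rec500 = EmgRecording(emg500, TARGET_RATE, recording.muscle_names, recording.terrain)

    heel500 = resample_signal(pressure.heel, pressure.rate, TARGET_RATE)
    toe500 = resample_signal(pressure.toe, pressure.rate, TARGET_RATE)
    pres500 = PressureTrace(np.clip(heel500, 0, None), np.clip(toe500, 0, None), TARGET_RATE)

    events = detect_gait_events(pres500)
    cycles = segment_cycles(events, recording.terrain)
    windows = [w for c in cycles for w in extract_windows(rec500, c)]
    return rec500, events, windows
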