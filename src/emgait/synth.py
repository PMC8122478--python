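"""Synthetic gait-structured sEMG and foot-pressure generator.

Surface EMG during walking is well approximated, for classification
purposes, as a band-limited stochastic carrier amplitude-modulated by a
muscle-activation envelope that is (quasi-)periodic in the gait cycle.
This module generates such signals for five lower-limb/back muscles
(tibialis anterior, medial gastrocnemius, rectus femoris, vastus
lateralis, erector spinalis) on three terrains (level ground, stair
ascent, stair descent), together with heel/toe foot-pressure traces and
ground-truth gait events, so that every downstream stage — event
detection, cycle segmentation, windowing, feature extraction, selection
and classification — can be exercised against a known answer.

The signal model per channel is

    x(t) = envelope(terrain, muscle, phase(t)) * carrier(t)
           + baseline_noise + powerline + motion_artifact

where the carrier is Gaussian white noise band-passed to ``noise_band``
(default 20–150 Hz), the powerline term is a 50 Hz sinusoid plus
harmonics, and the motion artifact is a low-pass (<10 Hz) random walk.
Envelopes are sums of Gaussian bumps in phase-fraction coordinates
(phase 0 = heel strike, periodic with the cycle), with per-terrain bump
placements so that the same muscle activates at different points of the
cycle on different terrains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import signal as sps

TERRAINS = ("level_ground", "stair_ascent", "stair_descent")
MUSCLES = ("TA", "MG", "RF", "VL", "ES")

#: Default activation bumps, (center phase-fraction, width, amplitude).
#: Phase 0 is heel strike; toe off falls near the stance fraction.
#: Placements follow the usual gait-EMG picture: TA active at heel strike
#: and during swing clearance, MG at push-off, RF/VL in loading response
#: (strongly on stairs), ES biphasic around the two support transitions.
DEFAULT_ENVELOPES: dict[tuple[str, str], tuple[tuple[float, float, float], ...]] = {
    ("level_ground", "TA"): ((0.05, 0.06, 1.0), (0.75, 0.10, 0.8)),
    ("level_ground", "MG"): ((0.45, 0.10, 1.2),),
    ("level_ground", "RF"): ((0.08, 0.07, 0.9), (0.62, 0.08, 0.5)),
    ("level_ground", "VL"): ((0.10, 0.08, 1.0),),
    ("level_ground", "ES"): ((0.02, 0.05, 0.7), (0.52, 0.06, 0.6)),
    ("stair_ascent", "TA"): ((0.10, 0.08, 0.6), (0.80, 0.08, 1.0)),
    ("stair_ascent", "MG"): ((0.35, 0.12, 1.4),),
    ("stair_ascent", "RF"): ((0.15, 0.10, 1.3), (0.70, 0.08, 0.7)),
    ("stair_ascent", "VL"): ((0.20, 0.12, 1.4),),
    ("stair_ascent", "ES"): ((0.05, 0.06, 0.9), (0.55, 0.08, 0.8)),
    ("stair_descent", "TA"): ((0.03, 0.05, 1.2), (0.70, 0.12, 0.6)),
    ("stair_descent", "MG"): ((0.10, 0.06, 0.5), (0.55, 0.08, 0.9)),
    ("stair_descent", "RF"): ((0.30, 0.15, 1.1),),
    ("stair_descent", "VL"): ((0.05, 0.10, 1.5), (0.40, 0.10, 0.8)),
    ("stair_descent", "ES"): ((0.02, 0.05, 0.5), (0.50, 0.10, 0.9)),
}

DEFAULT_STANCE_FRACTION = {
    "level_ground": 0.60,
    "stair_ascent": 0.62,
    "stair_descent": 0.58,
}


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimulationConfig:
    """Parameters of one synthetic walking session.

    Defaults describe self-paced walking: 1.1 s cycles with 5% duration
    CV, stance fractions near 0.6, EMG sampled at 1926 Hz and foot
    pressure at 148 Hz, carrier band 20–150 Hz, and interference levels
    (powerline, motion artifact) small relative to unit-scale envelopes.
    """

    n_cycles_per_terrain: int = 40
    cycle_duration_mean: float = 1.1
    cycle_duration_cv: float = 0.05
    stance_fraction: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STANCE_FRACTION)
    )
    emg_rate: float = 1926.0
    pressure_rate: float = 148.0
    envelope_profiles: dict[tuple[str, str], tuple[tuple[float, float, float], ...]] = field(
        default_factory=lambda: dict(DEFAULT_ENVELOPES)
    )
    noise_band: tuple[float, float] = (20.0, 150.0)
    baseline_noise_amp: float = 0.05
    powerline_amp: float = 0.10
    powerline_harmonic_decay: float = 0.5
    artifact_amp: float = 0.20
    amplitude_jitter_cv: float = 0.10
    pressure_rise_time: float = 0.010
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cycles_per_terrain < 1:
            raise ConfigurationError("n_cycles_per_terrain must be >= 1")
        if self.cycle_duration_mean <= 0:
            raise ConfigurationError("cycle_duration_mean must be positive")
        if self.cycle_duration_cv < 0:
            raise ConfigurationError("cycle_duration_cv must be >= 0")
        for terrain, frac in self.stance_fraction.items():
            if not 0.0 < frac < 1.0:
                raise ConfigurationError(
                    f"stance_fraction[{terrain!r}] must lie in (0, 1)"
                )
        lo, hi = self.noise_band
        if not 0.0 < lo < hi < self.emg_rate / 2:
            raise ConfigurationError(
                "noise_band must satisfy 0 < low < high < emg_rate/2"
            )
        if self.emg_rate <= 0 or self.pressure_rate <= 0:
            raise ConfigurationError("sampling rates must be positive")


@dataclass
class EmgRecording:
    """Multichannel sEMG: ``samples`` is a (channels, time) array."""

    samples: np.ndarray
    rate: float
    muscle_names: tuple[str, ...]
    terrain: str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels, time) array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.rate


@dataclass
class PressureTrace:
    """Heel and toe insole pressure, nonnegative, common sampling rate."""

    heel: np.ndarray
    toe: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.heel = np.asarray(self.heel, dtype=float)
        self.toe = np.asarray(self.toe, dtype=float)
        if self.heel.shape != self.toe.shape:
            raise ValueError("heel and toe traces must have equal length")
        if self.rate <= 0:
            raise ValueError("rate must be positive")


@dataclass
class GroundTruth:
    """Simulator-known event times (seconds) and phase structure."""

    hs_times: np.ndarray
    to_times: np.ndarray
    ts_times: np.ndarray
    ho_times: np.ndarray

    def __post_init__(self) -> None:
        for name in ("hs_times", "to_times", "ts_times", "ho_times"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.size > 1 and not np.all(np.diff(arr) > 0):
                raise ValueError(f"{name} must be strictly increasing")


def activation_envelope(
    terrain: str,
    muscle: str,
    phase_fraction,
    profiles: dict | None = None,
) -> np.ndarray:
    """Muscle-activation amplitude at the given cycle phase fraction(s).

    The envelope is a sum of Gaussian bumps in phase coordinates, made
    periodic by evaluating each bump at the nearest wrapped distance, so
    the value at phase 0 equals the value at phase 1.
    """
    profiles = DEFAULT_ENVELOPES if profiles is None else profiles
    if terrain not in TERRAINS:
        raise ConfigurationError(f"unknown terrain {terrain!r}")
    if muscle not in MUSCLES:
        raise ConfigurationError(f"unknown muscle {muscle!r}")
    phase = np.asarray(phase_fraction, dtype=float)
    if np.any((phase < 0) | (phase > 1)):
        raise ValueError("phase_fraction must lie in [0, 1]")
    bumps = profiles.get((terrain, muscle), ())
    out = np.zeros_like(phase)
    for center, width, amp in bumps:
        d = phase - center
        d = d - np.round(d)  # wrapped distance in [-0.5, 0.5)
        out = out + amp * np.exp(-0.5 * (d / width) ** 2)
    return out


def _bandpass_noise(n: int, rate: float, band: tuple[float, float], rng) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to ``band``."""
    white = rng.standard_normal(n)
    sos = sps.butter(4, band, btype="bandpass", fs=rate, output="sos")
    x = sps.sosfiltfilt(sos, white)
    std = x.std()
    return x / std if std > 0 else x


def add_interference(
    x: np.ndarray,
    powerline_amp: float,
    artifact_amp: float,
    rate: float,
    seed: int,
    n_harmonics: int = 3,
    harmonic_decay: float = 0.5,
) -> np.ndarray:
    """Add 50 Hz powerline (plus harmonics) and a <10 Hz motion artifact.

    The artifact is a Gaussian random walk low-pass filtered below 10 Hz
    and scaled to ``artifact_amp`` RMS; the powerline component has the
    given amplitude at 50 Hz with geometrically decaying harmonics.
    Deterministic for a fixed seed. Output length equals input length.
    """
    if rate <= 100:
        raise ValueError("rate must exceed 100 Hz")
    x = np.asarray(x, dtype=float)
    n = x.size
    out = x.copy()
    t = np.arange(n) / rate
    if powerline_amp > 0:
        for k in range(1, n_harmonics + 1):
            f = 50.0 * k
            if f >= rate / 2:
                break
            out += powerline_amp * harmonic_decay ** (k - 1) * np.sin(
                2 * np.pi * f * t + 0.7 * k
            )
    if artifact_amp > 0:
        rng = np.random.default_rng(seed)
        walk = np.cumsum(rng.standard_normal(n))
        sos = sps.butter(4, 10.0, btype="lowpass", fs=rate, output="sos")
        art = sps.sosfiltfilt(sos, walk)
        art = art - art.mean()
        rms = np.sqrt(np.mean(art**2))
        if rms > 0:
            art = art * (artifact_amp / rms)
        out += art
    return out


def _cycle_durations(config: SimulationConfig, rng) -> np.ndarray:
    dur = config.cycle_duration_mean * (
        1.0 + config.cycle_duration_cv * rng.standard_normal(config.n_cycles_per_terrain)
    )
    return np.clip(dur, 0.5 * config.cycle_duration_mean, 1.5 * config.cycle_duration_mean)


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def generate_terrain(
    config: SimulationConfig, terrain: str, seed: int
) -> tuple[EmgRecording, PressureTrace, GroundTruth]:
    """Generate one continuous walking recording on a single terrain."""
    rng = np.random.default_rng(seed)
    durations = _cycle_durations(config, rng)
    # 0.5 s of quiet lead-in/out so the first/last windows fit comfortably
    pad = 0.5
    hs = pad + np.concatenate([[0.0], np.cumsum(durations[:-1])])
    stance = config.stance_fraction[terrain]
    to = hs + durations * stance
    # toe strike / heel off at fixed fractions of stance
    ts = hs + durations * stance * 0.25
    ho = hs + durations * stance * 0.80
    total = pad + float(np.sum(durations)) + pad

    n_emg = int(round(total * config.emg_rate))
    t_emg = np.arange(n_emg) / config.emg_rate

    # phase fraction at every EMG sample: 0 before first HS / after last cycle
    phase = np.zeros(n_emg)
    in_cycle = np.zeros(n_emg, dtype=bool)
    for start, dur in zip(hs, durations):
        m = (t_emg >= start) & (t_emg < start + dur)
        phase[m] = (t_emg[m] - start) / dur
        in_cycle[m] = True

    channels = np.zeros((len(MUSCLES), n_emg))
    for ci, muscle in enumerate(MUSCLES):
        env = np.zeros(n_emg)
        env[in_cycle] = activation_envelope(
            terrain, muscle, phase[in_cycle], config.envelope_profiles
        )
        if config.amplitude_jitter_cv > 0:
            # per-cycle multiplicative gain jitter
            gains = 1.0 + config.amplitude_jitter_cv * rng.standard_normal(len(hs))
            gains = np.clip(gains, 0.2, None)
            for start, dur, g in zip(hs, durations, gains):
                m = (t_emg >= start) & (t_emg < start + dur)
                env[m] *= g
        carrier = _bandpass_noise(n_emg, config.emg_rate, config.noise_band, rng)
        x = env * carrier
        if config.baseline_noise_amp > 0:
            x = x + config.baseline_noise_amp * _bandpass_noise(
                n_emg, config.emg_rate, config.noise_band, rng
            )
        x = add_interference(
            x,
            config.powerline_amp,
            config.artifact_amp,
            config.emg_rate,
            seed=int(rng.integers(2**31)),
            harmonic_decay=config.powerline_harmonic_decay,
        )
        channels[ci] = x

    # pressure traces: heel loaded HS -> HO, toe loaded TS -> TO (of the
    # NEXT stance's toe-off, i.e. within the same stance phase)
    n_p = int(round(total * config.pressure_rate))
    t_p = np.arange(n_p) / config.pressure_rate
    heel = np.zeros(n_p)
    toe = np.zeros(n_p)
    rt = config.pressure_rise_time
    for h, o in zip(hs, ho):
        heel += _smoothstep((t_p - h) / rt) - _smoothstep((t_p - (o - rt)) / rt)
    for s, o in zip(ts, to):
        toe += _smoothstep((t_p - s) / rt) - _smoothstep((t_p - (o - rt)) / rt)
    heel = np.clip(heel, 0.0, None)
    toe = np.clip(toe, 0.0, None)

    rec = EmgRecording(channels, config.emg_rate, MUSCLES, terrain)
    pres = PressureTrace(heel, toe, config.pressure_rate)
    truth = GroundTruth(hs_times=hs, to_times=to, ts_times=ts, ho_times=ho)
    return rec, pres, truth


def generate_session(
    config: SimulationConfig,
) -> dict[str, tuple[EmgRecording, PressureTrace, GroundTruth]]:
    """Generate one recording per terrain; bit-identical for a fixed seed."""
    root = np.random.default_rng(config.seed)
    seeds = root.integers(2**31, size=len(TERRAINS))
    return {
        terrain: generate_terrain(config, terrain, int(s))
        for terrain, s in zip(TERRAINS, seeds)
    }


def virtual_subjects(
    n_subjects: int = 3,
    base_config: SimulationConfig | None = None,
    seed: int = 0,
) -> list[SimulationConfig]:
    """Configurations for a small cohort of virtual subjects.

    Subjects share the envelope geometry but differ in overall per-muscle
    activation gain (±15% lognormal-ish jitter) and in all noise seeds,
    emulating inter-subject amplitude variability so that across-subject
    robustness statistics are nondegenerate.
    """
    base = base_config or SimulationConfig()
    rng = np.random.default_rng(seed)
    configs = []
    for si in range(n_subjects):
        profiles = {}
        for key, bumps in base.envelope_profiles.items():
            gain = float(np.exp(0.15 * rng.standard_normal()))
            profiles[key] = tuple((c, w, a * gain) for c, w, a in bumps)
        cfg = SimulationConfig(
            n_cycles_per_terrain=base.n_cycles_per_terrain,
            cycle_duration_mean=base.cycle_duration_mean,
            cycle_duration_cv=base.cycle_duration_cv,
            stance_fraction=dict(base.stance_fraction),
            emg_rate=base.emg_rate,
            pressure_rate=base.pressure_rate,
            envelope_profiles=profiles,
            noise_band=base.noise_band,
            baseline_noise_amp=base.baseline_noise_amp,
            powerline_amp=base.powerline_amp,
            artifact_amp=base.artifact_amp,
            amplitude_jitter_cv=base.amplitude_jitter_cv,
            seed=int(rng.integers(2**31)),
        )
        configs.append(cfg)
    return configs


def write_session(session, config: SimulationConfig, out_dir) -> None:
    """Write a generated session as per-terrain CSVs plus a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta: dict = {
        "emg_rate": config.emg_rate,
        "pressure_rate": config.pressure_rate,
        "muscles": list(MUSCLES),
        "seed": config.seed,
        "terrains": {},
    }
    for terrain, (rec, pres, truth) in session.items():
        t = np.arange(rec.samples.shape[1]) / rec.rate
        emg_cols = np.column_stack([t] + [rec.samples[i] for i in range(len(MUSCLES))])
        np.savetxt(
            out / f"emg_{terrain}.csv",
            emg_cols,
            delimiter=",",
            header="time_s," + ",".join(f"ch{i + 1}" for i in range(len(MUSCLES))),
            comments="",
        )
        tp = np.arange(pres.heel.size) / pres.rate
        np.savetxt(
            out / f"pressure_{terrain}.csv",
            np.column_stack([tp, pres.heel, pres.toe]),
            delimiter=",",
            header="time_s,heel,toe",
            comments="",
        )
        meta["terrains"][terrain] = {
            "hs_times": truth.hs_times.tolist(),
            "to_times": truth.to_times.tolist(),
            "ts_times": truth.ts_times.tolist(),
            "ho_times": truth.ho_times.tolist(),
        }
    (out / "session.json").write_text(json.dumps(meta, indent=1))
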