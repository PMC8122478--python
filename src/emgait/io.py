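"""Delimited-text interchange: session directories, window and feature CSVs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import AnalysisWindow, class_label
from .synth import EmgRecording, GroundTruth, MUSCLES, PressureTrace


def read_session(in_dir) -> dict[str, tuple[EmgRecording, PressureTrace, GroundTruth]]:
    """Read a simulator session directory written by ``synth.write_session``."""
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "session.json").read_text())
    out = {}
    for terrain, truth_d in meta["terrains"].items():
        emg = pd.read_csv(in_dir / f"emg_{terrain}.csv")
        pres = pd.read_csv(in_dir / f"pressure_{terrain}.csv")
        rec = EmgRecording(
            emg[[c for c in emg.columns if c != "time_s"]].to_numpy().T,
            meta["emg_rate"],
            tuple(meta["muscles"]),
            terrain,
        )
        pt = PressureTrace(pres["heel"].to_numpy(), pres["toe"].to_numpy(), meta["pressure_rate"])
        gt = GroundTruth(
            hs_times=np.asarray(truth_d["hs_times"]),
            to_times=np.asarray(truth_d["to_times"]),
            ts_times=np.asarray(truth_d["ts_times"]),
            ho_times=np.asarray(truth_d["ho_times"]),
        )
        out[terrain] = (rec, pt, gt)
    return out


def write_windows(windows: list[AnalysisWindow], path) -> None:
    """Long-format window CSV: one row per (window, channel, sample)."""
    rows = []
    for wid, w in enumerate(windows):
        n_ch, n_s = w.samples.shape
        for ci in range(n_ch):
            for si in range(n_s):
                rows.append(
                    (wid, w.terrain, w.kind, w.class_label, ci, si, w.samples[ci, si])
                )
    df = pd.DataFrame(
        rows,
        columns=["window_id", "terrain", "kind", "label", "channel", "sample_idx", "value"],
    )
    df.to_csv(path, index=False)


def read_windows(path) -> list[AnalysisWindow]:
    """Reconstruct AnalysisWindow objects from a long-format window CSV."""
    df = pd.read_csv(path)
    windows = []
    for wid, grp in df.groupby("window_id", sort=True):
        terrain = grp["terrain"].iloc[0]
        kind = grp["kind"].iloc[0]
        n_ch = int(grp["channel"].max()) + 1
        n_s = int(grp["sample_idx"].max()) + 1
        samples = np.zeros((n_ch, n_s))
        samples[grp["channel"].to_numpy(), grp["sample_idx"].to_numpy()] = grp["value"].to_numpy()
        windows.append(
            AnalysisWindow(
                kind=kind,
                terrain=terrain,
                start=0.0,
                duration=n_s / 500.0,
                samples=samples,
                class_label=class_label(terrain, kind),
            )
        )
    return windows
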