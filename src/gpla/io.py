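"""File formats: spike CSV, LFP HDF5, result JSON+HDF5.

Spikes travel as a columnar CSV with header ``unit_id,trial,time_s``; LFPs as
an HDF5 container with one real float dataset ``/lfp/trial_<k>`` per trial
and root attributes ``fs`` (Hz), ``channel_ids`` and optional ``coords``.
Results are split into a human-readable JSON (scalars, conventions, the
significance report) and an HDF5 holding the complex vectors and spectrum.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import GPLAResult
from .coupling import SpikeTrainSet
from .preprocess import RawLFP
from .significance import SignificanceReport

__all__ = [
    "read_spikes",
    "write_spikes",
    "read_lfp",
    "write_lfp",
    "write_result",
    "read_result",
]


def write_spikes(spikes: SpikeTrainSet, path: str | Path) -> None:
    rows = []
    for m, per_trial in enumerate(spikes.trains):
        for k, t in enumerate(per_trial):
            for idx in t:
                rows.append((spikes.units[m], k, idx / spikes.fs))
    pd.DataFrame(rows, columns=["unit_id", "trial", "time_s"]).to_csv(path, index=False)


def read_spikes(
    path: str | Path,
    fs: float,
    trial_lengths: list[int],
) -> SpikeTrainSet:
    """Read the spike CSV; schema violations raise with the offending row."""
    df = pd.read_csv(path)
    required = {"unit_id", "trial", "time_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    if df.empty:
        raise ValueError(f"{path}: spike file contains no spikes")
    n_trials = len(trial_lengths)
    for row in df.itertuples():
        if not 0 <= row.trial < n_trials:
            raise ValueError(f"{path} row {row.Index + 2}: trial {row.trial} out of range")
        length_s = trial_lengths[int(row.trial)] / fs
        if not 0 <= row.time_s < length_s + 0.5 / fs:
            raise ValueError(
                f"{path} row {row.Index + 2}: time {row.time_s}s outside trial "
                f"of length {length_s}s"
            )
    units = sorted(df["unit_id"].astype(str).unique())
    times = [
        [
            df[(df["unit_id"].astype(str) == u) & (df["trial"] == k)]["time_s"].to_numpy()
            for k in range(n_trials)
        ]
        for u in units
    ]
    return SpikeTrainSet.from_times(times, trial_lengths, fs, units=units)


def write_lfp(lfp: RawLFP, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        grp = f.create_group("lfp")
        for k, tr in enumerate(lfp.trials):
            grp.create_dataset(f"trial_{k}", data=tr.astype(np.float64))
        f.attrs["fs"] = lfp.fs
        f.attrs["channel_ids"] = [str(c) for c in lfp.channel_ids]
        if lfp.channel_coords is not None:
            f.create_dataset("coords", data=lfp.channel_coords)


def read_lfp(path: str | Path) -> RawLFP:
    with h5py.File(path, "r") as f:
        if "lfp" not in f:
            raise ValueError(f"{path}: missing /lfp group")
        keys = sorted(f["lfp"].keys(), key=lambda s: int(s.split("_")[1]))
        trials = [f["lfp"][k][()] for k in keys]
        fs = float(f.attrs["fs"])
        channel_ids = [str(c) for c in f.attrs.get("channel_ids", [])] or None
        coords = f["coords"][()] if "coords" in f else None
    return RawLFP(trials=trials, fs=fs, channel_ids=channel_ids, channel_coords=coords)


def _report_dict(report: SignificanceReport | None) -> dict | None:
    if report is None:
        return None
    return {
        "method": report.method,
        "significant": bool(report.significant),
        "p_value": report.p_value,
        "threshold": report.threshold,
        "statistic": report.statistic,
        "n_surrogates": report.n_surrogates,
        "jitter_window_s": report.jitter_window_s,
        "n_significant": report.n_significant,
        "seed": report.seed,
    }


def write_result(
    result: GPLAResult,
    report: SignificanceReport | None,
    path: str | Path,
) -> None:
    """Write ``<path>.json`` (scalars) and ``<path>.h5`` (vectors)."""
    path = Path(path)
    meta = {
        "gplv": result.gplv,
        "phi_d": result.phi_d,
        "band": list(result.band),
        "mode": result.mode,
        "whitened": result.whitened,
        "rotated": result.rotated,
        "unwhitened": result.unwhitened,
        "rescaled": result.rescaled,
        "n_channels": int(result.lfp_vector.shape[0]),
        "n_units": int(result.spike_vector.shape[0]),
        "significance": _report_dict(report),
    }
    if result.mode == "plv":
        meta["gplv_normalized"] = result.gplv_normalized
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    with h5py.File(path.with_suffix(".h5"), "w") as f:
        f.create_dataset("lfp_vector", data=result.lfp_vector)
        f.create_dataset("spike_vector", data=result.spike_vector)
        f.create_dataset("spectrum", data=result.spectrum)
        if result.unit_counts is not None:
            f.create_dataset("unit_counts", data=result.unit_counts)


def read_result(path: str | Path) -> tuple[dict, dict]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    with h5py.File(path.with_suffix(".h5"), "r") as f:
        arrays = {k: f[k][()] for k in f.keys()}
    return meta, arrays
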