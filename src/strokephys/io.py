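"""Readers and writers for the package's data containers.

Laminar recordings travel as HDF5 (one file per recording); trajectories,
platform traces and event tables as CSV with documented headers; ground
truth as JSON sidecars.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .behavior import PlatformTrial
from .ephys import LaminarRecording
from .kinematics import ReachTrajectory

__all__ = [
    "save_recording",
    "load_recording",
    "trajectory_to_csv",
    "trajectory_from_csv",
    "platform_trial_to_csv",
    "platform_trial_from_csv",
    "write_truth_json",
]


def save_recording(path: str | Path, rec: LaminarRecording) -> None:
    """Write a LaminarRecording to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("voltages", data=rec.voltages, compression="gzip")
        f.create_dataset("channel_depths", data=rec.channel_depths)
        f.create_dataset("stim_times", data=rec.stim_times)
        if rec.stim_intensities is not None:
            f.create_dataset("stim_intensities", data=rec.stim_intensities)
        f.attrs["sample_rate"] = rec.sample_rate
        f.attrs["condition"] = rec.condition
        f.attrs["isi_ms"] = -1 if rec.isi_ms is None else rec.isi_ms


def load_recording(path: str | Path) -> LaminarRecording:
    with h5py.File(path, "r") as f:
        isi = int(f.attrs["isi_ms"])
        return LaminarRecording(
            voltages=f["voltages"][...],
            sample_rate=float(f.attrs["sample_rate"]),
            channel_depths=f["channel_depths"][...],
            stim_times=f["stim_times"][...],
            stim_intensities=f["stim_intensities"][...] if "stim_intensities" in f else None,
            condition=str(f.attrs["condition"]),
            isi_ms=None if isi < 0 else isi,
        )


def trajectory_to_csv(path: str | Path, traj: ReachTrajectory) -> None:
    """Columns: t_s, x_mm, y_mm (+ header comment is left to the manifest)."""
    pd.DataFrame({"t_s": traj.t, "x_mm": traj.x, "y_mm": traj.y}).to_csv(path, index=False)


def trajectory_from_csv(path: str | Path, frame_rate: float | None = None,
                        **kwargs) -> ReachTrajectory:
    df = pd.read_csv(path)
    t = df["t_s"].to_numpy()
    if frame_rate is None:
        frame_rate = 1.0 / float(np.median(np.diff(t)))
    return ReachTrajectory(t=t, x=df["x_mm"].to_numpy(), y=df["y_mm"].to_numpy(),
                           frame_rate=frame_rate, **kwargs)


def platform_trial_to_csv(path: str | Path, trial: PlatformTrial) -> None:
    """Columns: t_s, force_N, position_mm."""
    pd.DataFrame({"t_s": trial.t, "force_N": trial.force,
                  "position_mm": trial.position}).to_csv(path, index=False)


def platform_trial_from_csv(path: str | Path, **kwargs) -> PlatformTrial:
    df = pd.read_csv(path)
    return PlatformTrial(t=df["t_s"].to_numpy(), force=df["force_N"].to_numpy(),
                         position=df["position_mm"].to_numpy(), **kwargs)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_truth_json(path: str | Path, truth) -> None:
    """Serialize a ground-truth record (dataclass or dict) as JSON."""
    Path(path).write_text(json.dumps(_jsonable(truth), indent=1, sort_keys=True))
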