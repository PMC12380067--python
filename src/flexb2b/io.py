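"""File formats: EEG trial sets as HDF5, trajectories as CSV, configs as YAML.

HDF5 layout for trial sets: ``/data`` (n_trials x channels x samples,
float32 microvolts), ``/labels`` (n_trials, int, -1 for unlabelled), file
attributes ``fs`` and ``channel_names``.  Trajectory CSV has the header
``t,x,y`` (seconds, millimetres).
"""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd
import yaml

from .synth import CHANNEL_NAMES, EEGTrial, Trajectory

__all__ = [
    "save_trials",
    "load_trials",
    "save_trajectory",
    "load_trajectory",
    "load_config",
    "save_config",
]


def save_trials(path, trials: list[EEGTrial]) -> None:
    if not trials:
        raise ValueError("no trials to save")
    fs = trials[0].fs
    names = trials[0].channel_names
    if any(t.fs != fs or t.channel_names != names for t in trials):
        raise ValueError("trials must share fs and montage")
    data = np.stack([t.data for t in trials]).astype(np.float32)
    labels = np.array([-1 if t.label is None else t.label for t in trials],
                      dtype=np.int64)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=data)
        f.create_dataset("labels", data=labels)
        f.attrs["fs"] = fs
        f.attrs["channel_names"] = list(names)


def load_trials(path) -> list[EEGTrial]:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        labels = f["labels"][()]
        fs = float(f.attrs["fs"])
        names = tuple(
            n.decode() if isinstance(n, bytes) else str(n)
            for n in f.attrs["channel_names"]
        )
    return [
        EEGTrial(d, fs=fs, channel_names=names,
                 label=None if l < 0 else int(l))
        for d, l in zip(data.astype(np.float64), labels)
    ]


def save_trajectory(path, traj: Trajectory) -> None:
    pd.DataFrame({"t": traj.t, "x": traj.x, "y": traj.y}).to_csv(
        path, index=False)


def load_trajectory(path) -> Trajectory:
    df = pd.read_csv(path)
    for col in ("t", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"trajectory CSV missing column {col!r}")
    return Trajectory(df["t"].to_numpy(), df["x"].to_numpy(),
                      df["y"].to_numpy())


def load_config(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


def save_config(path, cfg: dict) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(cfg, f, sort_keys=False)
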