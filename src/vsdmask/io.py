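"""Serialization of stacks, trial logs, templates and configs.

Stacks go to HDF5 (``frames`` dataset plus scalar attributes) or multi-page
TIFF; trial logs to CSV; decoder outputs to tidy CSV tables; configs to
YAML.
"""

from __future__ import annotations

import os

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .synth import ImageStack, TrialRecord


def save_stack_h5(path, stack: ImageStack, dataset: str = "frames"):
    with h5py.File(path, "w") as f:
        d = f.create_dataset(dataset, data=stack.frames, compression="gzip")
        d.attrs["frame_rate"] = stack.frame_rate
        d.attrs["onset_index"] = stack.onset_index
        d.attrs["is_dff"] = stack.is_dff
        d.attrs["baseline_window_ms"] = list(stack.baseline_window_ms)


def load_stack_h5(path, dataset: str = "frames") -> ImageStack:
    with h5py.File(path, "r") as f:
        d = f[dataset]
        return ImageStack(frames=d[...], frame_rate=float(d.attrs["frame_rate"]),
                          onset_index=int(d.attrs["onset_index"]),
                          is_dff=bool(d.attrs["is_dff"]),
                          baseline_window_ms=tuple(d.attrs["baseline_window_ms"]))


def save_stack_tiff(path, stack: ImageStack):
    tifffile.imwrite(path, stack.frames.astype(np.float32),
                     metadata={"frame_rate": stack.frame_rate,
                               "onset_index": stack.onset_index,
                               "is_dff": stack.is_dff})


def trial_log_frame(trials, stack_paths=None) -> pd.DataFrame:
    """Tidy trial log; ``stack_paths`` optionally maps trial index -> path."""
    rows = []
    for i, tr in enumerate(trials):
        s = tr.stimulus
        rows.append({
            "trial_id": i, "block": tr.block,
            "C_T": s.target_contrast, "theta_T": s.target_orientation,
            "C_B": s.background_contrast, "theta_B": s.background_orientation,
            "target_present": tr.target_present, "outcome": tr.outcome,
            "rt_ms": tr.reaction_time_ms,
            "stack_path": stack_paths.get(i) if stack_paths else None})
    return pd.DataFrame(rows)


def save_trial_log(path, trials, stack_paths=None):
    trial_log_frame(trials, stack_paths).to_csv(path, index=False)


def decoded_series_frame(series, trial_id=0) -> pd.DataFrame:
    """Long-format decoder output: (trial_id, t_ms, channel, value)."""
    vals = np.asarray(series.values, dtype=float)
    if vals.ndim == 1:
        return pd.DataFrame({"trial_id": trial_id, "t_ms": series.times_ms,
                             "channel": series.scale, "value": vals})
    frames = []
    for k, th in enumerate(series.channel_orientations):
        frames.append(pd.DataFrame({
            "trial_id": trial_id, "t_ms": series.times_ms,
            "channel": f"{th:+.0f}", "value": vals[:, k]}))
    return pd.concat(frames, ignore_index=True)


def save_yaml(path, obj):
    with open(path, "w") as f:
        yaml.safe_dump(obj, f, sort_keys=False)


def load_yaml(path):
    with open(path) as f:
        return yaml.safe_load(f)
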