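"""File formats: flat-binary recordings with JSON sidecars, CSV tables, YAML.

A recording is stored as little-endian float32, frame-interleaved (sample
t0 channel 0, t0 channel 1, ..., t1 channel 0, ...), next to a JSON sidecar
``<stem>.json`` holding the sampling rate, channel count, channel -> shank
map and any extra metadata (scenario, seed). Spikes are ``unit_id,time_s``
CSV; epochs are ``label,start_s,end_s`` CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import EpochSet, Recording

__all__ = [
    "save_recording",
    "load_recording",
    "save_spikes",
    "load_spikes",
    "save_epochs",
    "load_epochs",
    "load_config",
    "save_config",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def save_recording(rec: Recording, path: str | Path, extra: dict | None = None) -> None:
    path = Path(path)
    frames = np.ascontiguousarray(rec.samples.T, dtype="<f4")
    frames.tofile(path)
    meta = {
        "fs_hz": rec.fs,
        "n_channels": rec.n_channels,
        "channel_shank_map": rec.channel_shank_map.tolist(),
        "dtype": "<f4",
        "layout": "frame_interleaved",
    }
    if extra:
        meta.update(extra)
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def load_recording(path: str | Path) -> tuple[Recording, dict]:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    raw = np.fromfile(path, dtype=meta.get("dtype", "<f4"))
    n_ch = int(meta["n_channels"])
    if raw.size % n_ch:
        raise ValueError(f"{path}: size {raw.size} not divisible by {n_ch} channels")
    samples = raw.reshape(-1, n_ch).T.astype(float)
    rec = Recording(samples, fs=float(meta["fs_hz"]), channel_shank_map=meta["channel_shank_map"])
    return rec, meta


def save_spikes(spikes: dict[int, np.ndarray], path: str | Path) -> None:
    rows = [
        {"unit_id": int(u), "time_s": float(t)}
        for u in sorted(spikes)
        for t in np.asarray(spikes[u])
    ]
    pd.DataFrame(rows, columns=["unit_id", "time_s"]).to_csv(path, index=False)


def load_spikes(path: str | Path) -> dict[int, np.ndarray]:
    frame = pd.read_csv(path)
    return {
        int(u): np.sort(grp["time_s"].to_numpy(float))
        for u, grp in frame.groupby("unit_id")
    }


def save_epochs(epochs: EpochSet, path: str | Path, fs: float) -> None:
    epochs.to_csv(path, fs)


def load_epochs(path: str | Path, fs: float) -> EpochSet:
    return EpochSet.from_csv(path, fs)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
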