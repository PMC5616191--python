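"""Core data containers: multichannel recordings and labeled epoch windows.

A :class:`Recording` is a dense ``(n_channels, n_samples)`` array with a sampling
rate and a channel -> shank map describing the probe geometry. An
:class:`EpochSet` is a list of labeled, fixed-length, half-open sample windows
(``[start, end)``, 0-based) -- typically ``run`` and ``baseline`` 5-s epochs that
form the paired unit of every condition comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Recording", "EpochSet"]


@dataclass
class Recording:
    """Continuous multichannel signal with probe geometry.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Signal in acquisition units.
    fs : float
        Sampling rate in Hz.
    channel_shank_map : array-like of int
        Shank (or tetrode) id of each channel.
    """

    samples: np.ndarray
    fs: float
    channel_shank_map: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.channel_shank_map = np.asarray(self.channel_shank_map, dtype=int)
        if self.channel_shank_map.shape != (self.samples.shape[0],):
            raise ValueError(
                "channel_shank_map must assign exactly one shank per channel: "
                f"{self.channel_shank_map.shape[0]} entries for "
                f"{self.samples.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def shanks(self) -> np.ndarray:
        """Sorted unique shank ids."""
        return np.unique(self.channel_shank_map)

    def shank_channels(self, shank: int) -> np.ndarray:
        """Indices of the channels on one shank."""
        idx = np.flatnonzero(self.channel_shank_map == shank)
        if idx.size == 0:
            raise KeyError(f"no channels on shank {shank!r}")
        return idx

    def with_samples(self, samples: np.ndarray, channel_shank_map=None) -> "Recording":
        """Copy with new sample data (and optionally a new channel map)."""
        cmap = self.channel_shank_map if channel_shank_map is None else channel_shank_map
        return Recording(samples=np.asarray(samples, float), fs=self.fs, channel_shank_map=cmap)


@dataclass
class EpochSet:
    """Labeled fixed-length windows in sample coordinates.

    Intervals are half-open ``[start, end)``; within a label, epochs must not
    overlap.
    """

    labels: np.ndarray
    starts: np.ndarray
    ends: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if not (self.labels.shape == self.starts.shape == self.ends.shape):
            raise ValueError("labels, starts and ends must have equal length")
        if np.any(self.ends <= self.starts):
            raise ValueError("epochs must satisfy end > start")
        for lab in np.unique(self.labels.astype(str)):
            sel = self.labels == lab
            s, e = self.starts[sel], self.ends[sel]
            order = np.argsort(s)
            if np.any(s[order][1:] < e[order][:-1]):
                raise ValueError(f"overlapping epochs within label {lab!r}")

    def __len__(self) -> int:
        return self.labels.size

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    def select(self, label: str) -> "EpochSet":
        sel = self.labels == label
        return EpochSet(self.labels[sel], self.starts[sel], self.ends[sel])

    def slice_array(self, samples: np.ndarray) -> np.ndarray:
        """Cut epochs out of a ``(n_channels, n_samples)`` array.

        Returns
        -------
        ndarray, shape (n_epochs, n_channels, epoch_len)
            Requires all epochs to share one length.
        """
        lens = np.unique(self.lengths)
        if lens.size != 1:
            raise ValueError("slice_array requires equal-length epochs")
        samples = np.atleast_2d(samples)
        return np.stack([samples[:, s:e] for s, e in zip(self.starts, self.ends)])

    def subset(self, keep: np.ndarray) -> "EpochSet":
        keep = np.asarray(keep)
        return EpochSet(self.labels[keep], self.starts[keep], self.ends[keep])

    # --- serialization (seconds on disk, samples in memory) -----------------

    def to_frame(self, fs: float) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels.astype(str),
                "start_s": self.starts / fs,
                "end_s": self.ends / fs,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, fs: float) -> "EpochSet":
        starts = np.rint(frame["start_s"].to_numpy() * fs).astype(np.int64)
        ends = np.rint(frame["end_s"].to_numpy() * fs).astype(np.int64)
        return cls(frame["label"].to_numpy(), starts, ends)

    def to_csv(self, path: str | Path, fs: float) -> None:
        self.to_frame(fs).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, fs: float) -> "EpochSet":
        return cls.from_frame(pd.read_csv(path), fs)
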