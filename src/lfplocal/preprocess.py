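"""Preprocessing: decimation, filtering, artifact flags, epochs, rereferencing.

All filtering is zero-phase (forward-backward), so a passband tone and its
filtered version are aligned to the sample. Rereferencing comes in the two
derivations used to probe volume conduction: bipolar against a neighboring
shank, and common-average across shanks. Both remove any component that is
present with equal gain on all channels.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import signal

from .containers import EpochSet, Recording

__all__ = [
    "downsample",
    "bandpass_notch",
    "detect_artifacts",
    "extract_epochs",
    "rereference_bipolar",
    "rereference_car",
]

log = logging.getLogger(__name__)


def downsample(rec: Recording, target_fs: float) -> Recording:
    """Anti-alias low-pass then integer decimation to ``target_fs``.

    The anti-alias filter is a zero-phase FIR low-pass with cutoff
    ``0.4 * target_fs``. The sampling factor must be an integer; the output
    length is ``floor(n_samples / factor)``.
    """
    ratio = rec.fs / target_fs
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        near = [rec.fs / q for q in (max(1, factor - 1), max(1, factor), factor + 1)]
        raise ValueError(
            f"cannot decimate {rec.fs} Hz to {target_fs} Hz by an integer factor; "
            f"nearest valid target rates: {sorted(set(near), reverse=True)}"
        )
    if factor == 1:
        return rec.with_samples(rec.samples.copy())
    numtaps = 16 * factor + 1
    fir = signal.firwin(numtaps, 0.4 * target_fs, fs=rec.fs)
    filtered = signal.filtfilt(fir, [1.0], rec.samples, axis=1)
    n_out = rec.n_samples // factor
    out = filtered[:, : n_out * factor : factor]
    return Recording(out, fs=target_fs, channel_shank_map=rec.channel_shank_map)


def bandpass_notch(
    rec: Recording,
    band: tuple[float, float] = (0.1, 250.0),
    notch_base: float = 50.0,
    notch_q: float = 30.0,
) -> Recording:
    """Zero-phase band-pass plus notches at integer multiples of ``notch_base``.

    Defaults follow common practice for LFP work: 0.1-250 Hz passband and
    notches at mains frequency and harmonics up to Nyquist.
    """
    lo, hi = band
    nyq = rec.fs / 2.0
    if not (0.0 < lo < hi < nyq):
        raise ValueError(f"band {band} must lie inside (0, {nyq}) Hz")
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    out = signal.sosfiltfilt(sos, rec.samples, axis=1)
    k = 1
    while k * notch_base < nyq:
        b, a = signal.iirnotch(k * notch_base, notch_q, fs=rec.fs)
        out = signal.filtfilt(b, a, out, axis=1)
        k += 1
    return rec.with_samples(out)


def detect_artifacts(rec: Recording, epochs: EpochSet, z_thresh: float = 4.0) -> np.ndarray:
    """Flag epochs whose per-channel signal variance is an outlier.

    For every epoch and channel the variance over time is computed; variances
    are z-scored across epochs (per channel) and an epoch is flagged when any
    channel exceeds ``|z| > z_thresh``. The data are not modified.

    Returns
    -------
    ndarray of bool, shape (n_epochs,)
    """
    if len(epochs) == 0:
        raise ValueError("empty epoch list")
    if len(epochs) < 2:
        raise ValueError("artifact z-scoring needs at least 2 epochs")
    var = np.stack(
        [rec.samples[:, s:e].var(axis=1) for s, e in zip(epochs.starts, epochs.ends)]
    )  # (n_epochs, n_channels)
    mu = var.mean(axis=0)
    sd = var.std(axis=0, ddof=1)
    sd[sd == 0] = np.inf
    z = (var - mu) / sd
    flags = np.max(np.abs(z), axis=1) > z_thresh
    if flags.any():
        log.info("flagged %d/%d epochs as artifacts (|z| > %g)", flags.sum(), len(epochs), z_thresh)
    return flags


def extract_epochs(
    trials: pd.DataFrame,
    epoch_len: float = 5.0,
    fs: float = 1250.0,
    min_trial_duration: float = 7.0,
) -> EpochSet:
    """Cut run and baseline epochs out of a trial table.

    Per included trial: the run epoch is the last ``epoch_len`` seconds before
    the stop-area entry, ``[stop_entry - epoch_len, stop_entry)``; the baseline
    epoch is the ``epoch_len`` seconds immediately preceding trial start,
    required to lie inside the preceding intertrial interval. Trials with
    duration <= ``min_trial_duration`` seconds or flagged incorrect are
    excluded; trials whose intertrial is too short for a baseline are dropped
    with a warning.

    Expected columns: ``trial_id, trial_start_s, stop_entry_s,
    intertrial_start_s, intertrial_end_s, correct``.
    """
    need = {"trial_start_s", "stop_entry_s", "intertrial_start_s", "intertrial_end_s"}
    missing = need - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    ep_n = int(round(epoch_len * fs))
    labels: list[str] = []
    starts: list[int] = []
    for _, row in trials.iterrows():
        if "correct" in trials.columns and not bool(row["correct"]):
            continue
        if row["stop_entry_s"] - row["trial_start_s"] <= min_trial_duration:
            continue
        base_start = row["trial_start_s"] - epoch_len
        if base_start < row["intertrial_start_s"] - 1e-9 or row["trial_start_s"] > row["intertrial_end_s"] + 1e-9:
            warnings.warn(
                f"trial {row.get('trial_id', '?')}: intertrial shorter than "
                f"{epoch_len} s, trial dropped",
                stacklevel=2,
            )
            continue
        run_start = int(round((row["stop_entry_s"] - epoch_len) * fs))
        if run_start < 0:
            warnings.warn(
                f"trial {row.get('trial_id', '?')}: run epoch precedes recording start, dropped",
                stacklevel=2,
            )
            continue
        labels.extend(["run", "baseline"])
        starts.extend([run_start, int(round(base_start * fs))])
    starts_arr = np.asarray(starts, dtype=np.int64)
    return EpochSet(np.asarray(labels, dtype=object), starts_arr, starts_arr + ep_n)


def rereference_bipolar(rec: Recording, target_shank: int, reference_shank: int) -> Recording:
    """Bipolar derivation: target-shank channels minus the reference-shank mean.

    Channels outside the target shank are dropped. Any signal appearing with
    equal gain on both shanks cancels exactly.
    """
    if target_shank == reference_shank:
        raise ValueError("target and reference shank must differ")
    tgt = rec.shank_channels(target_shank)
    ref = rec.shank_channels(reference_shank)
    ref_mean = rec.samples[ref].mean(axis=0)
    out = rec.samples[tgt] - ref_mean
    return Recording(out, fs=rec.fs, channel_shank_map=rec.channel_shank_map[tgt])


def rereference_car(rec: Recording) -> Recording:
    """Common-average reference across shanks.

    One representative mean trace per shank is computed, the across-shank mean
    of those is subtracted from every channel. Idempotent on already-centered
    data.
    """
    shanks = rec.shanks()
    if shanks.size < 2:
        raise ValueError("common-average reference needs at least 2 shanks")
    shank_means = np.stack([rec.samples[rec.shank_channels(s)].mean(axis=0) for s in shanks])
    grand = shank_means.mean(axis=0)
    return rec.with_samples(rec.samples - grand)
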