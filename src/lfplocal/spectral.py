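"""Multitaper power and cross-spectral estimation (DPSS tapers).

Two smoothing semantics are supported:

``fixed_bandwidth``
    One DPSS taper family for the whole epoch with half-bandwidth
    ``smoothing_param`` Hz; spectra are read off a zero-padded FFT by
    nearest-bin lookup. This is the mode fed to the spectral-factorization
    (Granger) path, which needs a single self-consistent uniform grid.

``proportional``
    A frequency-proportional half-bandwidth ``W(f) = smoothing_param * f``
    with a fixed taper count: at each analysis frequency a separate DPSS
    family is built and the single-bin tapered DFT is evaluated there. This
    reproduces the "smoothing of 0.8*f with seven tapers" style of estimate
    common in the LFP literature.

PSD normalization is one-sided density (units^2/Hz): the integral of a
white-noise PSD over [0, fs/2] equals its variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.signal.windows import dpss

from .containers import Recording

__all__ = [
    "SpectralConfig",
    "SpectralEstimate",
    "CrossSpectralMatrix",
    "multitaper_psd",
    "multitaper_csd",
    "whiten_psd",
    "spectrogram",
]


@dataclass(frozen=True)
class SpectralConfig:
    """Frequency grid and taper parameters for multitaper estimation.

    ``smoothing_param`` is the half-bandwidth in Hz in ``fixed_bandwidth``
    mode, or the dimensionless proportionality factor in ``proportional``
    mode (half-bandwidth ``W(f) = smoothing_param * f``).
    """

    f_start: float = 1.0
    f_stop: float = 20.0
    f_step: float = 0.2
    n_tapers: int = 7
    smoothing_mode: str = "proportional"
    smoothing_param: float = 0.8

    def __post_init__(self) -> None:
        if self.f_step <= 0:
            raise ValueError("f_step must be positive")
        if self.n_tapers < 1:
            raise ValueError("n_tapers must be >= 1")
        if self.smoothing_mode not in ("fixed_bandwidth", "proportional"):
            raise ValueError(f"unknown smoothing_mode {self.smoothing_mode!r}")
        if self.f_start <= 0:
            raise ValueError("grid must start above 0 Hz")

    @property
    def grid(self) -> np.ndarray:
        return np.arange(self.f_start, self.f_stop + self.f_step / 2.0, self.f_step)


@dataclass
class SpectralEstimate:
    """Per-frequency power density with bookkeeping."""

    freqs: np.ndarray
    power: np.ndarray
    n_epochs: int
    whitened: bool = False

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, float)
        self.power = np.asarray(self.power, float)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must have equal length")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")


@dataclass
class CrossSpectralMatrix:
    """Per-frequency Hermitian cross-spectral matrix.

    ``S`` has shape ``(n_freqs, n_channels, n_channels)``. ``kind`` records the
    scale convention: ``"onesided_density"`` (default, units^2/Hz, DC/Nyquist
    not doubled) or ``"discrete"`` (raw discrete-time spectrum, the convention
    used internally by the spectral factorization).
    """

    freqs: np.ndarray
    S: np.ndarray
    fs: float
    n_epochs: int = 0
    n_tapers: int = 0
    kind: str = "onesided_density"

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, float)
        self.S = np.asarray(self.S, complex)
        if self.S.ndim != 3 or self.S.shape[1] != self.S.shape[2]:
            raise ValueError("S must have shape (n_freqs, n_channels, n_channels)")
        if self.S.shape[0] != self.freqs.size:
            raise ValueError("S and freqs disagree on the number of frequencies")

    @property
    def n_channels(self) -> int:
        return self.S.shape[1]

    def psd(self, channel: int) -> SpectralEstimate:
        p = np.maximum(self.S[:, channel, channel].real, 0.0)
        return SpectralEstimate(self.freqs, p, n_epochs=self.n_epochs)

    def hermitian_error(self) -> float:
        return float(np.max(np.abs(self.S - np.conj(np.swapaxes(self.S, 1, 2)))))


# ---------------------------------------------------------------------------
# taper machinery


def _next_pow2(n: int) -> int:
    return 1 << (int(n - 1).bit_length())


@lru_cache(maxsize=8)
def _fixed_tapers(n: int, fs: float, w_hz: float, k: int) -> np.ndarray:
    nw = w_hz * n / fs
    tapers = np.atleast_2d(dpss(n, nw, Kmax=k))
    # unit energy per taper
    return tapers / np.linalg.norm(tapers, axis=1, keepdims=True)


@lru_cache(maxsize=4)
def _proportional_bank(n: int, fs: float, cfg_key: tuple) -> np.ndarray:
    """Complex matrix of taper-modulated exponentials, shape (F*K, n).

    Row ``f*K + k`` is ``taper_k^{(f)}(t) * exp(-2i*pi*f*t/fs)``; multiplying
    it with an epoch gives the k-th tapered DFT coefficient at grid
    frequency f.
    """
    f_start, f_stop, f_step, n_tapers, factor = cfg_key
    freqs = SpectralConfig(f_start, f_stop, f_step, n_tapers, "proportional", factor).grid
    t = np.arange(n)
    bank = np.empty((freqs.size * n_tapers, n), dtype=complex)
    for j, f in enumerate(freqs):
        nw = max(factor * f * n / fs, 1.0)  # clamp: dpss needs NW >= 1
        tap = np.atleast_2d(dpss(n, nw, Kmax=n_tapers))
        tap = tap / np.linalg.norm(tap, axis=1, keepdims=True)
        phasor = np.exp(-2j * np.pi * f * t / fs)
        bank[j * n_tapers : (j + 1) * n_tapers] = tap * phasor
    return bank


def _check_epochs(epoch_matrix: np.ndarray, fs: float, cfg: SpectralConfig) -> np.ndarray:
    epoch_matrix = np.atleast_2d(np.asarray(epoch_matrix, float))
    n = epoch_matrix.shape[-1]
    # the grid step may be up to twice as fine as the Rayleigh resolution 1/T
    # (zero-padded nearest-bin lookup); anything finer is unresolvable
    if n / fs < 1.0 / (2.0 * cfg.f_step):
        raise ValueError(
            f"epoch of {n / fs:.3g} s cannot resolve a {cfg.f_step} Hz grid "
            f"(needs >= {1.0 / (2.0 * cfg.f_step):.3g} s)"
        )
    if cfg.smoothing_mode == "fixed_bandwidth":
        nw = cfg.smoothing_param * n / fs
        if cfg.n_tapers > 2 * nw - 1:
            raise ValueError(
                f"{cfg.n_tapers} tapers exceed 2NW-1 = {2 * nw - 1:.2f} for "
                f"half-bandwidth {cfg.smoothing_param} Hz on a {n / fs:.3g}-s epoch"
            )
    return epoch_matrix


def _coefficients_proportional(
    epoch_matrix: np.ndarray, fs: float, cfg: SpectralConfig
) -> np.ndarray:
    """Tapered DFT coefficients on the config grid, shape (n_epochs, F, K)."""
    n = epoch_matrix.shape[-1]
    key = (cfg.f_start, cfg.f_stop, cfg.f_step, cfg.n_tapers, cfg.smoothing_param)
    bank = _proportional_bank(n, fs, key)
    coef = bank @ epoch_matrix.T  # (F*K, n_epochs)
    nf = cfg.grid.size
    return coef.T.reshape(epoch_matrix.shape[0], nf, cfg.n_tapers)


def _psd_fixed_full(
    epoch_matrix: np.ndarray, fs: float, cfg: SpectralConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Full-grid fixed-bandwidth PSD: (freqs_full, power_full)."""
    n = epoch_matrix.shape[-1]
    nfft = _next_pow2(n)
    tapers = _fixed_tapers(n, fs, cfg.smoothing_param, cfg.n_tapers)
    x = np.fft.rfft(epoch_matrix[:, None, :] * tapers[None, :, :], n=nfft, axis=-1)
    p = (2.0 / fs) * np.mean(np.abs(x) ** 2, axis=(0, 1))
    p[0] *= 0.5
    if nfft % 2 == 0:
        p[-1] *= 0.5
    return np.fft.rfftfreq(nfft, 1.0 / fs), p


def _nearest_bins(freqs_full: np.ndarray, grid: np.ndarray) -> np.ndarray:
    df = freqs_full[1] - freqs_full[0]
    idx = np.rint(grid / df).astype(int)
    return np.clip(idx, 0, freqs_full.size - 1)


def multitaper_psd(
    epoch_matrix: np.ndarray, fs: float, cfg: SpectralConfig | None = None
) -> SpectralEstimate:
    """Multitaper PSD averaged over epochs and tapers.

    Parameters
    ----------
    epoch_matrix : ndarray, shape (n_epochs, n_samples)
        Equal-length epochs of one channel.
    """
    cfg = cfg or SpectralConfig()
    epoch_matrix = _check_epochs(epoch_matrix, fs, cfg)
    if cfg.smoothing_mode == "fixed_bandwidth":
        freqs_full, p_full = _psd_fixed_full(epoch_matrix, fs, cfg)
        idx = _nearest_bins(freqs_full, cfg.grid)
        power = p_full[idx]
    else:
        coef = _coefficients_proportional(epoch_matrix, fs, cfg)
        power = (2.0 / fs) * np.mean(np.abs(coef) ** 2, axis=(0, 2))
    return SpectralEstimate(cfg.grid, power, n_epochs=epoch_matrix.shape[0])


def multitaper_csd(
    epoch_tensor: np.ndarray,
    fs: float,
    cfg: SpectralConfig | None = None,
    full_grid: bool = False,
    pad_factor: int = 4,
) -> CrossSpectralMatrix:
    """Multitaper cross-spectral matrix averaged over epochs x tapers.

    ``S_ij(f) = < X_i(f) conj(X_j(f)) >``; the diagonal equals
    :func:`multitaper_psd` of the corresponding channel under the same config.

    With ``full_grid=True`` (fixed-bandwidth mode only) the matrix is returned
    on the complete uniform FFT grid spanning [0, fs/2] -- the form required by
    the spectral factorization behind Granger causality. ``pad_factor``
    oversamples that grid (zero-padding) so the causal factor of an *estimated*
    (hence rough) spectrum fits inside half the lag circle; without it the
    factorization stalls at a truncation floor.
    """
    cfg = cfg or SpectralConfig()
    epoch_tensor = np.asarray(epoch_tensor, float)
    if epoch_tensor.ndim != 3:
        raise ValueError("epoch_tensor must have shape (n_epochs, n_channels, n_samples)")
    n_ep, n_ch, n = epoch_tensor.shape
    if n_ch < 2:
        raise ValueError("cross-spectra need at least 2 channels (use multitaper_psd)")
    _check_epochs(epoch_tensor[:, 0, :], fs, cfg)
    if full_grid:
        if cfg.smoothing_mode != "fixed_bandwidth":
            raise ValueError("full-grid CSD requires fixed_bandwidth smoothing")
        nfft = max(1, int(pad_factor)) * _next_pow2(n)
        tapers = _fixed_tapers(n, fs, cfg.smoothing_param, cfg.n_tapers)
        x = np.fft.rfft(epoch_tensor[:, :, None, :] * tapers[None, None, :, :], n=nfft, axis=-1)
        # (n_ep, n_ch, K, F) -> S (F, C, C)
        S = np.einsum("eckf,edkf->fcd", x, np.conj(x)) * (2.0 / (fs * n_ep * cfg.n_tapers))
        S[0] *= 0.5
        if nfft % 2 == 0:
            S[-1] *= 0.5
        freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    elif cfg.smoothing_mode == "fixed_bandwidth":
        nfft = _next_pow2(n)
        tapers = _fixed_tapers(n, fs, cfg.smoothing_param, cfg.n_tapers)
        x = np.fft.rfft(epoch_tensor[:, :, None, :] * tapers[None, None, :, :], n=nfft, axis=-1)
        freqs_full = np.fft.rfftfreq(nfft, 1.0 / fs)
        idx = _nearest_bins(freqs_full, cfg.grid)
        xg = x[..., idx]  # (n_ep, n_ch, K, F)
        S = np.einsum("eckf,edkf->fcd", xg, np.conj(xg)) * (2.0 / (fs * n_ep * cfg.n_tapers))
        freqs = cfg.grid
    else:
        coef = np.stack(
            [_coefficients_proportional(epoch_tensor[:, c, :], fs, cfg) for c in range(n_ch)],
            axis=1,
        )  # (n_ep, n_ch, F, K)
        S = np.einsum("ecfk,edfk->fcd", coef, np.conj(coef)) * (2.0 / (fs * n_ep * cfg.n_tapers))
        freqs = cfg.grid
    return CrossSpectralMatrix(
        freqs=freqs, S=S, fs=fs, n_epochs=n_ep, n_tapers=cfg.n_tapers, kind="onesided_density"
    )


def whiten_psd(est: SpectralEstimate) -> SpectralEstimate:
    """Multiply the power at each frequency by the frequency squared.

    Compensates the ~1/f^2 background of LFP spectra so narrowband peaks stand
    out. Invertible on the stored grid (divide by f^2).
    """
    if np.any(est.freqs <= 0):
        raise ValueError("whitening requires strictly positive frequencies")
    return SpectralEstimate(
        est.freqs, est.power * est.freqs**2, n_epochs=est.n_epochs, whitened=True
    )


def spectrogram(
    rec: Recording,
    cfg: SpectralConfig,
    window: float,
    step: float,
    channel: int = 0,
    db_floor: float = -120.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sliding-window multitaper power in decibels.

    Returns
    -------
    times : ndarray
        Window centers in seconds.
    freqs : ndarray
        The config grid.
    tf : ndarray, shape (n_times, n_freqs)
        ``10*log10`` power, clipped below at ``db_floor`` dB.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    win_n = int(round(window * rec.fs))
    if win_n > rec.n_samples:
        raise ValueError("window longer than the recording")
    step_n = max(1, int(round(step * rec.fs)))
    starts = np.arange(0, rec.n_samples - win_n + 1, step_n)
    x = rec.samples[channel]
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # dpss concentration warnings on tiny NW
        for s in starts:
            est = multitaper_psd(x[s : s + win_n][None, :], rec.fs, cfg)
            rows.append(est.power)
    tf = np.asarray(rows)
    floor_lin = 10.0 ** (db_floor / 10.0)
    tf = 10.0 * np.log10(np.maximum(tf, floor_lin))
    times = (starts + win_n / 2) / rec.fs
    return times, cfg.grid, tf
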