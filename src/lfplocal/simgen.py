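"""Synthetic multichannel LFPs and spike trains with known ground truth.

The generator emulates the structure of a treadmill session: 5-s "run" and
"baseline" epochs that differ in theta (~8 Hz) amplitude; several channels
receiving *instantaneous* scaled copies of one or more distant narrowband
sources (volume conduction) plus independent local white noise; optionally a
lagged directed coupling between a "striatum" and a "cortex" channel group
(a stable vector autoregression); and spike trains whose instantaneous rate is
von Mises-modulated by a source's theta phase.

Ground truth (scenario, all specs, seed) travels with the dataset so that the
downstream verdict can be scored.

Phase convention (used identically here and in :mod:`lfplocal.spikelfp`):
phase in degrees, 0 deg at the oscillation peak, increasing with time,
reported in (-180, 180].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal
from scipy.special import i0

from .containers import EpochSet, Recording

__all__ = [
    "SourceSpec",
    "MixingMap",
    "CouplingSpec",
    "SpikeModSpec",
    "SessionConfig",
    "SyntheticDataset",
    "ar2_coefficients",
    "simulate_theta_source",
    "simulate_var",
    "simulate_spike_train",
    "simulate_session",
    "wrap_degrees",
]

_SCENARIOS = ("volume_conduction", "lagged_coupling", "mixed")


def wrap_degrees(phase: np.ndarray) -> np.ndarray:
    """Wrap angles in degrees to the interval (-180, 180]."""
    return (np.asarray(phase, float) - 180.0) % -360.0 + 180.0


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class SourceSpec:
    """A distant field generator: narrowband AR(2) oscillator or broadband noise.

    ``amplitude_run``/``amplitude_baseline`` are the stationary standard
    deviations of the source during run and baseline epochs (signal units);
    the run/baseline contrast is a per-epoch step, with no ramps.
    """

    center_freq: float
    bandwidth: float
    amplitude_run: float = 1.0
    amplitude_baseline: float = 1.0
    kind: str = "narrowband_ar2"

    def __post_init__(self) -> None:
        if self.center_freq <= 0 or self.bandwidth <= 0:
            raise ValueError("center_freq and bandwidth must be positive")
        if self.amplitude_run < 0 or self.amplitude_baseline < 0:
            raise ValueError("amplitudes must be nonnegative")
        if self.kind not in ("narrowband_ar2", "broadband_noise"):
            raise ValueError(f"unknown source kind {self.kind!r}")


@dataclass
class MixingMap:
    """Instantaneous (zero-lag) gain matrix mapping sources onto channels."""

    gains: np.ndarray  # (n_channels, n_sources)

    def __post_init__(self) -> None:
        self.gains = np.atleast_2d(np.asarray(self.gains, dtype=float))
        if not np.all(np.isfinite(self.gains)):
            raise ValueError("mixing gains must be finite")

    @property
    def n_channels(self) -> int:
        return self.gains.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gains.shape[1]


def _companion(coeffs: np.ndarray) -> np.ndarray:
    """Companion matrix of a VAR(p) coefficient array (p, n, n)."""
    p, n, _ = coeffs.shape
    comp = np.zeros((n * p, n * p))
    comp[:n, :] = np.concatenate(list(coeffs), axis=1)
    if p > 1:
        comp[n:, : n * (p - 1)] = np.eye(n * (p - 1))
    return comp


@dataclass
class CouplingSpec:
    """Stable VAR ground truth for lagged (directed) coupling.

    ``var_coeffs[k]`` multiplies the state at lag ``k+1``. ``lag_step`` records
    the dominant interaction delay in samples (informational; the delay itself
    lives in the coefficient array).
    """

    var_coeffs: np.ndarray  # (order, n, n)
    noise_cov: np.ndarray  # (n, n)
    lag_step: int = 1

    def __post_init__(self) -> None:
        self.var_coeffs = np.asarray(self.var_coeffs, dtype=float)
        if self.var_coeffs.ndim != 3 or self.var_coeffs.shape[1] != self.var_coeffs.shape[2]:
            raise ValueError("var_coeffs must have shape (order, n, n)")
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        if not np.allclose(self.noise_cov, self.noise_cov.T):
            raise ValueError("noise_cov must be symmetric")
        if np.any(np.linalg.eigvalsh(self.noise_cov) <= 0):
            raise ValueError("noise_cov must be positive-definite")
        rho = self.spectral_radius()
        if rho >= 1.0:
            raise ValueError(f"unstable VAR: companion spectral radius {rho:.4f} >= 1")

    @property
    def order(self) -> int:
        return self.var_coeffs.shape[0]

    @property
    def dim(self) -> int:
        return self.var_coeffs.shape[1]

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(_companion(self.var_coeffs)))))


@dataclass(frozen=True)
class SpikeModSpec:
    """Phase-modulated unit: von Mises rate modulation around a source's phase.

    ``source_index < n_sources`` refers to a :class:`SourceSpec`; larger values
    index the components of the lagged-coupling VAR (``n_sources + k`` is
    latent component ``k``).
    """

    base_rate: float
    kappa: float
    pref_phase: float  # degrees in (-180, 180]
    source_index: int = 0

    def __post_init__(self) -> None:
        if self.base_rate < 0:
            raise ValueError("base_rate must be nonnegative")
        if self.kappa < 0:
            raise ValueError("kappa must be nonnegative")


# ---------------------------------------------------------------------------
# elementary generators


def ar2_coefficients(center_freq: float, bandwidth: float, fs: float) -> tuple[float, float]:
    """AR(2) coefficients placing a complex pole pair at ``center_freq``.

    Pole modulus ``r = exp(-pi * bandwidth / fs)`` so that ``bandwidth`` is the
    approximate -3 dB width of the spectral peak; pole angle
    ``2*pi*center_freq/fs``.
    """
    r = math.exp(-math.pi * bandwidth / fs)
    theta = 2.0 * math.pi * center_freq / fs
    return 2.0 * r * math.cos(theta), -(r * r)


def _ar2_stationary_var(a1: float, a2: float) -> float:
    """Stationary variance of x_t = a1 x_{t-1} + a2 x_{t-2} + e_t, Var e = 1."""
    return (1.0 - a2) / ((1.0 + a2) * ((1.0 - a2) ** 2 - a1 ** 2))


def simulate_theta_source(
    spec: SourceSpec,
    duration: float,
    fs: float,
    seed: int,
    amplitude: float | None = None,
) -> np.ndarray:
    """Simulate one source as a zero-mean stochastic series.

    For ``narrowband_ar2`` the series is an AR(2) process driven by white
    noise, scaled so its stationary standard deviation equals ``amplitude``
    (default ``spec.amplitude_run``); its spectral peak sits at
    ``spec.center_freq``. ``broadband_noise`` is white Gaussian noise of the
    same standard deviation.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if fs <= 2.0 * (spec.center_freq + spec.bandwidth):
        raise ValueError(
            f"sampling rate {fs} Hz too low for a source at "
            f"{spec.center_freq} Hz (bandwidth {spec.bandwidth} Hz): "
            f"need fs > {2.0 * (spec.center_freq + spec.bandwidth)} Hz"
        )
    amp = spec.amplitude_run if amplitude is None else float(amplitude)
    n = int(round(duration * fs))
    if amp == 0.0:
        return np.zeros(n)
    rng = np.random.default_rng(seed)
    if spec.kind == "broadband_noise":
        return amp * rng.standard_normal(n)
    a1, a2 = ar2_coefficients(spec.center_freq, spec.bandwidth, fs)
    # burn-in ~10 envelope decay times so the start is stationary
    burn = max(100, int(10.0 * fs / (math.pi * spec.bandwidth)))
    eps = rng.standard_normal(n + burn)
    x = signal.lfilter([1.0], [1.0, -a1, -a2], eps)[burn:]
    return amp / math.sqrt(_ar2_stationary_var(a1, a2)) * x


def simulate_var(coupling: CouplingSpec, n_samples: int, fs: float, seed: int) -> np.ndarray:
    """Simulate a realization of a stable VAR, shape ``(dim, n_samples)``.

    A burn-in of at least 10x the model order (and at least 500 samples) is
    discarded so the returned stretch is effectively stationary.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    rng = np.random.default_rng(seed)
    p, d = coupling.order, coupling.dim
    burn = max(10 * p, 500)
    total = n_samples + burn
    chol = np.linalg.cholesky(coupling.noise_cov)
    eps = rng.standard_normal((total, d)) @ chol.T
    # only the lags with nonzero coefficient matrices enter the recursion
    nz_lags = np.flatnonzero([np.any(coupling.var_coeffs[k]) for k in range(p)]) + 1
    x = _var_recursion(coupling.var_coeffs, eps, nz_lags.astype(np.int64))
    return x[burn:].T


def _var_recursion_py(coeffs: np.ndarray, eps: np.ndarray, nz_lags: np.ndarray) -> np.ndarray:
    x = eps.copy()
    total = eps.shape[0]
    for t in range(total):
        for k in nz_lags:
            if k <= t:
                x[t] += coeffs[k - 1] @ x[t - k]
    return x


try:  # sequential recursion: JIT-compiled when numba is available
    from numba import njit

    _var_recursion = njit(cache=False)(_var_recursion_py)
except ImportError:  # pragma: no cover
    _var_recursion = _var_recursion_py


def simulate_spike_train(
    phase_series: np.ndarray,
    mod: SpikeModSpec,
    fs: float,
    seed: int,
) -> np.ndarray:
    """Inhomogeneous Poisson spikes phase-locked to an oscillation.

    Intensity ``lambda(t) = base_rate * exp(kappa*cos(phi(t) - theta)) / I0(kappa)``
    (marginal mean rate = base_rate for uniform phase), sampled by
    Lewis-Shedler thinning with envelope rate ``base_rate*exp(kappa)/I0(kappa)``.

    Parameters
    ----------
    phase_series : ndarray
        Oscillation phase in degrees, one value per sample.
    """
    phase_series = np.asarray(phase_series, float)
    duration = phase_series.size / fs
    if mod.base_rate == 0.0:
        return np.array([])
    rng = np.random.default_rng(seed)
    i0k = float(i0(mod.kappa))
    rate_max = mod.base_rate * math.exp(mod.kappa) / i0k
    n_cand = rng.poisson(rate_max * duration)
    t_cand = np.sort(rng.uniform(0.0, duration, size=n_cand))
    # interpolate the unwrapped phase at candidate times (degrees)
    unwrapped = np.unwrap(np.deg2rad(phase_series))
    phi = np.interp(t_cand * fs, np.arange(phase_series.size), unwrapped)
    delta = phi - math.radians(mod.pref_phase)
    accept_p = np.exp(mod.kappa * (np.cos(delta) - 1.0))
    keep = rng.uniform(size=n_cand) < accept_p
    return t_cand[keep]


# ---------------------------------------------------------------------------
# session assembly


@dataclass
class SessionConfig:
    """Everything needed to build one synthetic session.

    ``channel_shank_map`` fixes the probe layout; ``shank_structures`` labels
    each shank ``"striatum"`` or ``"cortex"``. ``noise_std`` is the standard
    deviation of the independent local white noise per channel (scalar or one
    value per channel).
    """

    scenario: str
    sources: list[SourceSpec]
    mixing: MixingMap | None
    channel_shank_map: Sequence[int]
    n_trials: int = 20
    epoch_len: float = 5.0
    gap_len: float = 1.0
    fs: float = 1250.0
    seed: int = 0
    coupling: CouplingSpec | None = None
    coupling_gains: np.ndarray | None = None  # (n_channels, coupling_dim)
    spike_specs: list[SpikeModSpec] = field(default_factory=list)
    noise_std: float | np.ndarray = 0.1
    shank_structures: dict[int, str] | None = None

    def __post_init__(self) -> None:
        if self.scenario not in _SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; expected one of {_SCENARIOS}")
        self.channel_shank_map = np.asarray(self.channel_shank_map, dtype=int)
        n_ch = self.channel_shank_map.size
        if self.scenario == "volume_conduction":
            if self.coupling is not None or self.coupling_gains is not None:
                raise ValueError("coupling specified under the volume_conduction scenario")
        else:
            if self.coupling is None or self.coupling_gains is None:
                raise ValueError(f"scenario {self.scenario!r} requires coupling and coupling_gains")
            self.coupling_gains = np.atleast_2d(np.asarray(self.coupling_gains, float))
            if self.coupling_gains.shape != (n_ch, self.coupling.dim):
                raise ValueError(
                    f"coupling_gains shape {self.coupling_gains.shape} inconsistent with "
                    f"{n_ch} channels x VAR dim {self.coupling.dim}"
                )
        if self.sources:
            if self.mixing is None:
                raise ValueError("sources given but no mixing map")
            if self.mixing.gains.shape != (n_ch, len(self.sources)):
                raise ValueError(
                    f"mixing gains shape {self.mixing.gains.shape} inconsistent with "
                    f"{n_ch} channels x {len(self.sources)} sources"
                )
        n_latent = 0 if self.coupling is None else self.coupling.dim
        for spk in self.spike_specs:
            if not (0 <= spk.source_index < len(self.sources) + n_latent):
                raise ValueError(f"spike source_index {spk.source_index} out of range")

    @property
    def n_channels(self) -> int:
        return int(np.asarray(self.channel_shank_map).size)


@dataclass
class SyntheticDataset:
    """A generated session plus its ground truth."""

    recording: Recording
    spikes: dict[int, np.ndarray]  # unit id -> spike times (s)
    epochs: EpochSet
    truth: dict

    def epoch_tensor(self, label: str) -> np.ndarray:
        return self.epochs.select(label).slice_array(self.recording.samples)


def _session_layout(cfg: SessionConfig) -> tuple[EpochSet, int]:
    """Baseline / gap / run / gap per trial, with a 1-s lead-in."""
    fs = cfg.fs
    ep_n = int(round(cfg.epoch_len * fs))
    gap_n = int(round(cfg.gap_len * fs))
    lead = int(round(1.0 * fs))
    labels, starts = [], []
    cursor = lead
    for _ in range(cfg.n_trials):
        labels.append("baseline")
        starts.append(cursor)
        cursor += ep_n + gap_n
        labels.append("run")
        starts.append(cursor)
        cursor += ep_n + gap_n
    starts = np.asarray(starts, dtype=np.int64)
    epochs = EpochSet(np.asarray(labels, dtype=object), starts, starts + ep_n)
    return epochs, cursor + lead


def _amplitude_envelope(spec: SourceSpec, epochs: EpochSet, n_samples: int) -> np.ndarray:
    env = np.full(n_samples, spec.amplitude_baseline)
    run = epochs.select("run")
    for s, e in zip(run.starts, run.ends):
        env[s:e] = spec.amplitude_run
    return env


def _analytic_phase_deg(series: np.ndarray) -> np.ndarray:
    """Instantaneous phase (degrees, 0 at peak) via the analytic signal."""
    return wrap_degrees(np.rad2deg(np.angle(signal.hilbert(series))))


def simulate_session(cfg: SessionConfig) -> SyntheticDataset:
    """Build a full synthetic session from a :class:`SessionConfig`.

    Channels are ``mixing @ (sources * envelope) + local noise`` and, under the
    ``lagged_coupling``/``mixed`` scenarios, additionally
    ``coupling_gains @ var_realization``. Same config (including seed) yields a
    bit-identical dataset.
    """
    epochs, n_samples = _session_layout(cfg)
    fs = cfg.fs
    duration = n_samples / fs
    n_ch = cfg.n_channels
    ss = np.random.SeedSequence(cfg.seed)
    child = ss.spawn(len(cfg.sources) + 3 + len(cfg.spike_specs))

    data = np.zeros((n_ch, n_samples))
    phase_bank: list[np.ndarray] = []
    for k, spec in enumerate(cfg.sources):
        seed_k = child[k].generate_state(1)[0]
        unit = simulate_theta_source(spec, duration, fs, int(seed_k), amplitude=1.0)
        unit = unit[:n_samples]
        if spec.kind == "narrowband_ar2":
            phase_bank.append(_analytic_phase_deg(unit))
        else:
            phase_bank.append(np.zeros(n_samples))
        env = _amplitude_envelope(spec, epochs, n_samples)
        data += np.outer(cfg.mixing.gains[:, k], unit * env)

    if cfg.coupling is not None:
        seed_v = int(child[len(cfg.sources)].generate_state(1)[0])
        latent = simulate_var(cfg.coupling, n_samples, fs, seed_v)
        data += cfg.coupling_gains @ latent
        for comp in range(cfg.coupling.dim):
            phase_bank.append(_analytic_phase_deg(latent[comp]))

    seed_noise = int(child[len(cfg.sources) + 1].generate_state(1)[0])
    noise_std = np.broadcast_to(np.asarray(cfg.noise_std, float), (n_ch,))
    rng = np.random.default_rng(seed_noise)
    data += noise_std[:, None] * rng.standard_normal((n_ch, n_samples))

    spikes: dict[int, np.ndarray] = {}
    for u, spk in enumerate(cfg.spike_specs):
        seed_u = int(child[len(cfg.sources) + 3 + u].generate_state(1)[0])
        spikes[u] = simulate_spike_train(phase_bank[spk.source_index], spk, fs, seed_u)

    rec = Recording(samples=data, fs=fs, channel_shank_map=cfg.channel_shank_map)
    truth = {
        "scenario": cfg.scenario,
        "seed": cfg.seed,
        "config": cfg,
        "shank_structures": cfg.shank_structures,
    }
    return SyntheticDataset(recording=rec, spikes=spikes, epochs=epochs, truth=truth)
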