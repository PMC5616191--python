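"""Generator contracts: spectral placement, VAR moments, spike modulation."""

import numpy as np
import pytest

from lfplocal import (
    CouplingSpec,
    MixingMap,
    SessionConfig,
    SourceSpec,
    SpikeModSpec,
    simulate_session,
    simulate_spike_train,
    simulate_theta_source,
    simulate_var,
)
from lfplocal.simgen import _analytic_phase_deg, ar2_coefficients, wrap_degrees
from lfplocal.spectral import SpectralConfig, multitaper_psd, whiten_psd


class TestThetaSource:
    def test_spectral_peak_at_center_freq(self):
        spec = SourceSpec(8.0, 1.0)
        x = simulate_theta_source(spec, 100.0, 1250.0, seed=7)
        cfg = SpectralConfig(1.0, 20.0, 0.2, 7, "fixed_bandwidth", 0.8)
        est = multitaper_psd(x.reshape(20, -1), 1250.0, cfg)
        assert abs(est.freqs[np.argmax(est.power)] - 8.0) <= cfg.f_step + 1e-9

    def test_amplitude_sets_stationary_std(self):
        x = simulate_theta_source(SourceSpec(8.0, 1.0, amplitude_run=2.0), 200.0, 1250.0, seed=3)
        assert x.std() == pytest.approx(2.0, rel=0.05)
        assert abs(x.mean()) < 0.1

    def test_zero_amplitude_gives_zero_series(self):
        x = simulate_theta_source(SourceSpec(8.0, 1.0), 5.0, 1250.0, seed=0, amplitude=0.0)
        assert not x.any()

    def test_determinism_and_seed_sensitivity(self):
        spec = SourceSpec(8.0, 1.0)
        a = simulate_theta_source(spec, 2.0, 1250.0, seed=5)
        b = simulate_theta_source(spec, 2.0, 1250.0, seed=5)
        c = simulate_theta_source(spec, 2.0, 1250.0, seed=6)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_aliasing_precondition(self):
        with pytest.raises(ValueError, match="sampling rate"):
            simulate_theta_source(SourceSpec(8.0, 1.0), 1.0, fs=15.0, seed=0)

    def test_pole_placement(self):
        a1, a2 = ar2_coefficients(8.0, 1.0, 1250.0)
        roots = np.roots([1.0, -a1, -a2])
        angle_hz = abs(np.angle(roots[0])) * 1250.0 / (2 * np.pi)
        assert angle_hz == pytest.approx(8.0, abs=1e-6)
        assert abs(roots[0]) == pytest.approx(np.exp(-np.pi * 1.0 / 1250.0), abs=1e-9)


class TestSimulateVar:
    def test_white_noise_case(self):
        cp = CouplingSpec(np.zeros((1, 2, 2)), np.eye(2))
        x = simulate_var(cp, 40_000, 100.0, seed=1)
        cov = np.cov(x)
        assert np.allclose(cov, np.eye(2), atol=4.0 / np.sqrt(40_000))

    def test_ar1_yule_walker(self):
        cp = CouplingSpec(np.array([[[0.9]]]), np.eye(1))
        x = simulate_var(cp, 200_000, 100.0, seed=2)[0]
        assert x.var() == pytest.approx(1.0 / (1 - 0.81), rel=0.05)
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert r1 == pytest.approx(0.9, abs=0.01)

    def test_delayed_drive_shows_in_cross_correlation(self):
        lag = 5
        coeffs = np.zeros((lag, 2, 2))
        coeffs[lag - 1, 1, 0] = 0.9
        cp = CouplingSpec(coeffs, np.eye(2), lag_step=lag)
        x = simulate_var(cp, 50_000, 100.0, seed=3)
        xc = np.correlate(x[1] - x[1].mean(), x[0] - x[0].mean(), mode="full")
        best = np.argmax(xc) - (x.shape[1] - 1)
        assert best == lag

    def test_unstable_coefficients_rejected(self):
        with pytest.raises(ValueError, match="spectral radius"):
            CouplingSpec(np.array([[[1.05]]]), np.eye(1))


class TestSpikeTrain:
    def _phase(self, duration=200.0, fs=1250.0, freq=8.0):
        t = np.arange(int(duration * fs)) / fs
        return wrap_degrees(np.rad2deg(2 * np.pi * freq * t))

    def test_unmodulated_rate(self):
        phase = self._phase()
        spk = simulate_spike_train(phase, SpikeModSpec(5.0, 0.0, 0.0), 1250.0, seed=1)
        expect = 5.0 * 200.0
        assert abs(spk.size - expect) < 4 * np.sqrt(expect)

    def test_strong_modulation_circular_mean(self):
        phase = self._phase()
        spk = simulate_spike_train(phase, SpikeModSpec(5.0, 5.0, 90.0), 1250.0, seed=2)
        at = np.interp(spk * 1250.0, np.arange(phase.size), np.unwrap(np.deg2rad(phase)))
        mean = np.rad2deg(np.angle(np.exp(1j * at).mean()))
        assert mean == pytest.approx(90.0, abs=5.0)

    def test_zero_rate_empty(self):
        spk = simulate_spike_train(self._phase(1.0), SpikeModSpec(0.0, 1.0, 0.0), 1250.0, seed=0)
        assert spk.size == 0

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            SpikeModSpec(-1.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            SpikeModSpec(1.0, -0.5, 0.0)


class TestSimulateSession:
    def _vc_config(self, seed=0, noise=0.0, n_trials=3):
        return SessionConfig(
            scenario="volume_conduction",
            sources=[SourceSpec(8.0, 1.0, amplitude_run=1.0, amplitude_baseline=0.5)],
            mixing=MixingMap(np.ones((4, 1))),
            channel_shank_map=[0, 0, 1, 1],
            n_trials=n_trials,
            seed=seed,
            noise_std=noise,
        )

    def test_degenerate_mixing_identical_channels(self):
        ds = simulate_session(self._vc_config(noise=0.0))
        ref = ds.recording.samples[0]
        assert np.allclose(ds.recording.samples - ref, 0.0)

    def test_amplitude_square_law(self):
        cfg = SessionConfig(
            scenario="volume_conduction",
            sources=[SourceSpec(8.0, 1.0, amplitude_run=2.0, amplitude_baseline=1.0)],
            mixing=MixingMap(np.ones((1, 1))),
            channel_shank_map=[0],
            n_trials=20,
            seed=4,
            noise_std=0.0,
        )
        ds = simulate_session(cfg)
        scfg = SpectralConfig(1.0, 20.0, 0.2, 7, "fixed_bandwidth", 0.8)
        theta = (scfg.grid >= 6) & (scfg.grid <= 10)
        pw = {}
        for cond in ("run", "baseline"):
            est = whiten_psd(
                multitaper_psd(ds.epoch_tensor(cond)[:, 0, :], ds.recording.fs, scfg)
            )
            pw[cond] = est.power[theta].sum()
        assert pw["run"] / pw["baseline"] == pytest.approx(4.0, rel=0.25)

    def test_bit_identical_given_seed(self):
        a = simulate_session(self._vc_config(seed=9, noise=0.2))
        b = simulate_session(self._vc_config(seed=9, noise=0.2))
        assert np.array_equal(a.recording.samples, b.recording.samples)
        assert a.truth["scenario"] == "volume_conduction"

    def test_scenario_spec_mismatch_rejected(self):
        cp = CouplingSpec(np.zeros((1, 2, 2)), np.eye(2))
        with pytest.raises(ValueError, match="coupling"):
            SessionConfig(
                scenario="volume_conduction",
                sources=[SourceSpec(8.0, 1.0)],
                mixing=MixingMap(np.ones((2, 1))),
                channel_shank_map=[0, 1],
                coupling=cp,
                coupling_gains=np.ones((2, 2)),
            )
        with pytest.raises(ValueError, match="requires coupling"):
            SessionConfig(
                scenario="lagged_coupling",
                sources=[],
                mixing=None,
                channel_shank_map=[0, 1],
            )

    def test_epochs_do_not_overlap_and_have_exact_length(self):
        ds = simulate_session(self._vc_config(noise=0.1))
        assert set(ds.epochs.labels) == {"run", "baseline"}
        assert np.all(ds.epochs.lengths == round(5.0 * ds.recording.fs))

    def test_spike_phase_distribution_recovers_kappa(self):
        # generator/estimator round trip through the spike-LFP module
        from lfplocal.spikelfp import spike_phases, vonmises_fit

        src = simulate_theta_source(SourceSpec(8.0, 1.0), 300.0, 1250.0, seed=11)
        spk = simulate_spike_train(
            _analytic_phase_deg(src), SpikeModSpec(20.0, 2.0, 60.0), 1250.0, seed=12
        )
        fit = vonmises_fit(spike_phases(src, 1250.0, spk, 8.0, bandwidth=12.0))
        assert fit["kappa"] == pytest.approx(2.0, rel=0.1)
        assert fit["pref_phase"] == pytest.approx(60.0, abs=5.0)
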