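"""Filtering, epoching and rereferencing contracts."""

import numpy as np
import pandas as pd
import pytest

from lfplocal import (
    EpochSet,
    Recording,
    bandpass_notch,
    detect_artifacts,
    downsample,
    extract_epochs,
    rereference_bipolar,
    rereference_car,
)
from lfplocal.spectral import SpectralConfig, multitaper_psd


def _rec(samples, fs=1250.0, shanks=None):
    samples = np.atleast_2d(samples)
    shanks = shanks if shanks is not None else np.zeros(samples.shape[0], int)
    return Recording(samples, fs, shanks)


class TestDownsample:
    def test_factor_16(self):
        rec = _rec(np.random.default_rng(0).standard_normal((1, 200_000)), fs=20_000.0)
        out = downsample(rec, 1250.0)
        assert out.fs == 1250.0
        assert out.n_samples == 12_500

    def test_identity_factor(self):
        rec = _rec(np.arange(100.0))
        out = downsample(rec, rec.fs)
        assert np.array_equal(out.samples, rec.samples)

    def test_anti_aliasing_of_high_tone(self):
        fs = 20_000.0
        t = np.arange(int(4 * fs)) / fs
        rec = _rec(np.sin(2 * np.pi * 900.0 * t), fs=fs)
        out = downsample(rec, 1250.0)
        # output power anywhere below the new Nyquist must be <1% of tone power
        cfg = SpectralConfig(5.0, 620.0, 5.0, 5, "fixed_bandwidth", 10.0)
        est = multitaper_psd(out.samples[0].reshape(4, -1), 1250.0, cfg)
        assert est.power.max() * cfg.f_step < 0.01 * 0.5

    def test_non_integer_factor_rejected(self):
        rec = _rec(np.zeros(100), fs=1000.0)
        with pytest.raises(ValueError, match="nearest valid"):
            downsample(rec, 300.0)


class TestBandpassNotch:
    def test_dc_removed(self):
        rec = _rec(np.full(12_500, 10.0))
        out = bandpass_notch(rec)
        assert abs(out.samples.mean()) < 0.1

    def test_mains_tone_attenuated(self):
        t = np.arange(12_500) / 1250.0
        rec = _rec(np.sin(2 * np.pi * 50.0 * t))
        out = bandpass_notch(rec)
        mid = slice(3000, 9000)  # away from filtfilt edge transients
        ratio = out.samples[0, mid].std() / rec.samples[0, mid].std()
        assert ratio < 0.1  # >= 20 dB

    def test_theta_tone_preserved_zero_phase(self):
        t = np.arange(12_500) / 1250.0
        x = np.sin(2 * np.pi * 8.0 * t)
        out = bandpass_notch(_rec(x)).samples[0]
        mid = slice(2000, 10_500)
        assert out[mid].std() == pytest.approx(x[mid].std(), rel=0.05)
        xc = np.correlate(out[mid] - out[mid].mean(), x[mid] - x[mid].mean(), "full")
        assert np.argmax(xc) == len(out[mid]) - 1  # zero-sample lag

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError, match="band"):
            bandpass_notch(_rec(np.zeros(1000), fs=500.0), band=(0.1, 300.0))


class TestDetectArtifacts:
    def _epochs(self, n, length=1000):
        starts = np.arange(n) * length
        return EpochSet(np.array(["run"] * n, dtype=object), starts, starts + length)

    def test_clean_gaussian_epochs_unflagged(self, rng):
        rec = _rec(rng.standard_normal((3, 20_000)))
        flags = detect_artifacts(rec, self._epochs(20), z_thresh=4.0)
        assert not flags.any()

    def test_injected_variance_outlier_flagged(self, rng):
        x = rng.standard_normal((2, 20_000))
        x[:, 5000:6000] *= np.sqrt(10.0)
        flags = detect_artifacts(_rec(x), self._epochs(20), z_thresh=4.0)
        assert flags[5]
        assert flags.sum() == 1

    def test_too_few_epochs_rejected(self):
        rec = _rec(np.zeros((1, 1000)))
        with pytest.raises(ValueError):
            detect_artifacts(rec, self._epochs(1))
        with pytest.raises(ValueError, match="empty"):
            detect_artifacts(rec, self._epochs(0))


class TestExtractEpochs:
    def _table(self, **over):
        row = dict(
            trial_id=1,
            trial_start_s=20.0,
            stop_entry_s=32.0,
            intertrial_start_s=10.0,
            intertrial_end_s=20.0,
            correct=1,
        )
        row.update(over)
        return pd.DataFrame([row])

    def test_run_epoch_is_last_five_seconds_before_entry(self):
        eps = extract_epochs(self._table(), epoch_len=5.0, fs=1250.0)
        run = eps.select("run")
        assert run.starts[0] == round(27.0 * 1250)
        assert run.ends[0] == round(32.0 * 1250)
        base = eps.select("baseline")
        assert base.starts[0] == round(15.0 * 1250)

    def test_short_trial_excluded(self):
        eps = extract_epochs(self._table(stop_entry_s=26.5), fs=1250.0)
        assert len(eps) == 0

    def test_incorrect_trial_excluded(self):
        eps = extract_epochs(self._table(correct=0), fs=1250.0)
        assert len(eps) == 0

    def test_short_intertrial_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="intertrial"):
            eps = extract_epochs(self._table(intertrial_start_s=17.0), fs=1250.0)
        assert len(eps) == 0

    def test_epoch_at_recording_start(self):
        table = self._table(
            trial_start_s=5.0, stop_entry_s=13.0, intertrial_start_s=0.0, intertrial_end_s=5.0
        )
        eps = extract_epochs(table, fs=1250.0)
        assert eps.select("baseline").starts[0] == 0
        assert np.all(eps.lengths == round(5.0 * 1250))


class TestRereferencing:
    def test_identical_channels_cancel(self):
        x = np.tile(np.sin(np.arange(1000.0)), (4, 1))
        rec = _rec(x, shanks=[0, 0, 1, 1])
        assert np.allclose(rereference_bipolar(rec, 0, 1).samples, 0.0)
        assert np.allclose(rereference_car(rec).samples, 0.0)

    def test_bipolar_removes_common_source(self, rng):
        n = 125_000
        from lfplocal import SourceSpec, simulate_theta_source
        from lfplocal.connectivity import coherency, zero_lag_diagnostic
        from lfplocal.spectral import multitaper_csd

        s = simulate_theta_source(SourceSpec(8.0, 1.0), n / 1250.0, 1250.0, seed=5)
        chans = 0.8 * s + 0.3 * rng.standard_normal((4, n))
        rec = _rec(chans, shanks=[0, 0, 1, 1])
        out = rereference_bipolar(rec, 0, 1)
        # coherence of the derived signal with the source collapses
        tensor = np.stack([out.samples[0], s]).reshape(2, 20, -1).transpose(1, 0, 2)
        csd = multitaper_csd(tensor, 1250.0, SpectralConfig(1, 20, 0.2, 7, "fixed_bandwidth", 0.8))
        diag = zero_lag_diagnostic(coherency(csd, 0, 1), (6.0, 10.0))
        assert diag["mean_coherence"] < 0.1

    def test_car_centers_across_shanks(self, rng):
        rec = _rec(rng.standard_normal((4, 5000)), shanks=[0, 0, 1, 1])
        out = rereference_car(rec)
        shank_means = np.stack(
            [out.samples[out.shank_channels(s)].mean(axis=0) for s in out.shanks()]
        )
        assert np.allclose(shank_means.mean(axis=0), 0.0, atol=1e-12)

    def test_car_idempotent(self, rng):
        rec = _rec(rng.standard_normal((4, 2000)), shanks=[0, 0, 1, 1])
        once = rereference_car(rec)
        twice = rereference_car(once)
        assert np.allclose(once.samples, twice.samples)

    def test_invalid_shank_combinations(self):
        rec = _rec(np.zeros((2, 100)), shanks=[0, 0])
        with pytest.raises(ValueError, match="differ"):
            rereference_bipolar(rec, 0, 0)
        with pytest.raises(ValueError, match="2 shanks"):
            rereference_car(rec)
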