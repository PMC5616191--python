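"""Wilson factorization and Geweke decomposition against analytic references."""

import numpy as np
import pytest

from lfplocal import CouplingSpec, simulate_var
from lfplocal.granger import (
    decomposition_report,
    granger_spectral,
    parametric_geweke,
    var_csd,
    wilson_factorize,
)
from lfplocal.spectral import CrossSpectralMatrix, SpectralConfig, multitaper_csd

FS = 200.0


def _two_resonance_var():
    """VAR(2): two identical resonances, channel 0 drives channel 1."""
    coeffs = np.zeros((2, 2, 2))
    coeffs[0, 0, 0], coeffs[1, 0, 0] = 0.55, -0.8
    coeffs[0, 1, 1], coeffs[1, 1, 1] = 0.55, -0.8
    coeffs[0, 1, 0] = 0.2
    return coeffs, np.eye(2)


def _estimated_csd(coeffs, sigma, n_epochs, n_samples=1024, seed=11):
    cp = CouplingSpec(coeffs, sigma)
    x = simulate_var(cp, n_samples * n_epochs, FS, seed=seed)
    tensor = x.reshape(2, n_epochs, n_samples).transpose(1, 0, 2)
    cfg = SpectralConfig(1, 99, 1, 7, "fixed_bandwidth", 4.0 * FS / n_samples)
    return multitaper_csd(tensor, FS, cfg, full_grid=True)


class TestWilsonFactorize:
    def test_identity_spectrum(self):
        freqs = np.linspace(0.0, FS / 2, 129)
        S = np.tile(np.eye(2, dtype=complex), (129, 1, 1))
        csd = CrossSpectralMatrix(freqs, S, fs=FS, kind="discrete")
        fact = wilson_factorize(csd)
        assert np.allclose(fact.H, np.tile(np.eye(2), (129, 1, 1)), atol=1e-8)
        assert np.allclose(fact.Sigma, np.eye(2), atol=1e-8)

    def test_recovers_var_noise_covariance(self):
        coeffs, _ = _two_resonance_var()
        sigma = np.array([[1.0, 0.3], [0.3, 2.0]])
        freqs = np.linspace(0.0, FS / 2, 1025)
        csd = var_csd(coeffs, sigma, freqs, FS, kind="onesided_density")
        fact = wilson_factorize(csd)
        assert np.max(np.abs(fact.Sigma - sigma)) < 0.01 * np.max(np.abs(sigma))

    def test_reconstruction_contract(self):
        coeffs, sigma = _two_resonance_var()
        csd = _estimated_csd(coeffs, sigma, n_epochs=100)
        fact = wilson_factorize(csd)
        assert fact.residual < 1e-6

    def test_non_psd_input_names_frequency(self):
        freqs = np.linspace(0.0, FS / 2, 65)
        S = np.tile(np.eye(2, dtype=complex), (65, 1, 1))
        S[10] = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
        csd = CrossSpectralMatrix(freqs, S, fs=FS, kind="discrete")
        with pytest.raises(ValueError, match="positive semidefinite"):
            wilson_factorize(csd)

    def test_nonuniform_grid_rejected(self):
        freqs = np.array([0.0, 1.0, 3.0, 100.0])
        S = np.tile(np.eye(2, dtype=complex), (4, 1, 1))
        with pytest.raises(ValueError, match="uniform"):
            wilson_factorize(CrossSpectralMatrix(freqs, S, fs=FS, kind="discrete"))


class TestGrangerSpectral:
    def test_independent_channels_near_zero(self, rng):
        tensor = rng.standard_normal((100, 2, 512))
        cfg = SpectralConfig(1, 99, 1, 5, "fixed_bandwidth", 4.0 * FS / 512)
        csd = multitaper_csd(tensor, FS, cfg, full_grid=True)
        dec = granger_spectral(wilson_factorize(csd), pair=(0, 1))
        for comp in (dec.f_x2y, dec.f_y2x, dec.f_inst):
            assert np.nanpercentile(np.abs(comp), 95) < 0.05

    def test_directional_var_matches_parametric_oracle(self):
        coeffs, sigma = _two_resonance_var()
        csd = _estimated_csd(coeffs, sigma, n_epochs=200, n_samples=4096)
        dec = granger_spectral(wilson_factorize(csd), pair=(0, 1))
        par = parametric_geweke(coeffs, sigma, csd.freqs, FS, pair=(0, 1))
        kp = int(np.argmax(par.f_x2y))
        assert dec.f_x2y[kp] == pytest.approx(par.f_x2y[kp], rel=0.1)
        assert dec.f_x2y[kp] > 10 * dec.f_y2x[kp]

    def test_decomposition_identity_pointwise(self):
        coeffs, sigma = _two_resonance_var()
        csd = _estimated_csd(coeffs, sigma, n_epochs=50)
        dec = granger_spectral(wilson_factorize(csd), pair=(0, 1))
        assert dec.identity_deviation() < 1e-6

    def test_scale_invariance(self):
        coeffs, sigma = _two_resonance_var()
        csd = _estimated_csd(coeffs, sigma, n_epochs=50)
        dec_a = granger_spectral(wilson_factorize(csd), pair=(0, 1))
        scale = np.array([[9.0, 3.0], [3.0, 1.0]])  # channel gains 3 and 1
        csd_b = CrossSpectralMatrix(
            csd.freqs, csd.S * scale, fs=csd.fs, kind=csd.kind
        )
        dec_b = granger_spectral(wilson_factorize(csd_b), pair=(0, 1))
        # equivariance of the iteration is exact in theory; rounding paths differ,
        # leaving ~1e-7 absolute discrepancy on O(1) components
        for a, b in ((dec_a.f_x2y, dec_b.f_x2y), (dec_a.f_y2x, dec_b.f_y2x)):
            assert np.max(np.abs(a - b)) < 1e-6

    def test_estimate_converges_with_epochs(self):
        coeffs, sigma = _two_resonance_var()
        par = None
        errs = {}
        for n_ep in (50, 400):
            csd = _estimated_csd(coeffs, sigma, n_epochs=n_ep, seed=21)
            if par is None:
                par = parametric_geweke(coeffs, sigma, csd.freqs, FS, pair=(0, 1))
            dec = granger_spectral(wilson_factorize(csd), pair=(0, 1))
            sel = par.f_x2y > 0.05  # compare where the oracle has signal
            errs[n_ep] = np.mean(np.abs(dec.f_x2y[sel] - par.f_x2y[sel]))
        assert errs[400] < errs[50]


class TestDecompositionReport:
    def test_shares_sum_to_one(self):
        coeffs, sigma = _two_resonance_var()
        csd = _estimated_csd(coeffs, sigma, n_epochs=50)
        dec = granger_spectral(wilson_factorize(csd), pair=(0, 1))
        shares = decomposition_report(dec, (30.0, 50.0))
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-9)

    def test_directional_scenario_ranks_directions(self):
        coeffs, sigma = _two_resonance_var()
        csd = _estimated_csd(coeffs, sigma, n_epochs=50)
        dec = granger_spectral(wilson_factorize(csd), pair=(0, 1))
        shares = decomposition_report(dec, (30.0, 50.0))
        assert shares["share_x2y"] > shares["share_y2x"]

    def test_zero_total_flagged(self):
        freqs = np.linspace(0.0, FS / 2, 65)
        from lfplocal.granger import GrangerDecomposition

        z = np.zeros(65)
        dec = GrangerDecomposition(freqs, z, z, z, z)
        shares = decomposition_report(dec, (10.0, 20.0))
        assert all(np.isnan(v) for v in shares.values())

    def test_empty_band_rejected(self):
        from lfplocal.granger import GrangerDecomposition

        z = np.zeros(10)
        dec = GrangerDecomposition(np.linspace(0, 10, 10), z, z, z, z)
        with pytest.raises(ValueError, match="band"):
            decomposition_report(dec, (50.0, 60.0))
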