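"""Cross-spectra, imaginary coherency, MIC, Whittle VAR and TRGC."""

import numpy as np
import pytest
from scipy import signal

from ctxstn import coupling, spectral, synth
from ctxstn import preprocess as pp
from tests.conftest import make_recording


def toy_csd(s_ab, s_aa=1.0, s_bb=1.0, n_freqs=3):
    mats = np.zeros((n_freqs, 2, 2), dtype=complex)
    mats[:, 0, 0] = s_aa
    mats[:, 1, 1] = s_bb
    mats[:, 0, 1] = s_ab
    mats[:, 1, 0] = np.conj(s_ab)
    return coupling.CrossSpectralDensity(freqs=np.arange(n_freqs, dtype=float),
                                         matrices=mats)


class TestCsdMultitaper:
    def test_hermitian_and_diagonal_matches_psd(self):
        rng = np.random.default_rng(0)
        ep = pp.make_epochs(make_recording(rng.standard_normal((3, 20 * 500)),
                                           500.0, site_split=2))
        csd = coupling.csd_multitaper(ep)
        herm = np.abs(csd.matrices - csd.matrices.conj().transpose(0, 2, 1)).max()
        assert herm < 1e-12
        psd = spectral.multitaper_psd(ep)
        diag = np.real(np.einsum("fii->fi", csd.matrices)).T
        np.testing.assert_allclose(diag, psd.values, atol=1e-10)

    def test_identical_channels_unit_coherency(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(10 * 500)
        ep = pp.make_epochs(make_recording(np.vstack([x, x]), 500.0, site_split=1))
        csd = coupling.csd_multitaper(ep)
        s = csd.matrices
        coh = np.abs(s[:, 0, 1]) / np.sqrt(s[:, 0, 0].real * s[:, 1, 1].real)
        assert np.allclose(coh, 1.0, atol=1e-9)

    def test_quadrature_pair_purely_imaginary(self):
        fs, f0 = 500.0, 20.0
        t = np.arange(int(20 * fs)) / fs
        a = np.sin(2 * np.pi * f0 * t)
        b = np.sin(2 * np.pi * f0 * t - np.pi / 2)  # b lags a by 90 degrees
        ep = pp.make_epochs(make_recording(np.vstack([a, b]), fs, site_split=1))
        csd = coupling.csd_multitaper(ep)
        k = np.argmin(np.abs(csd.freqs - f0))
        c = csd.matrices[k, 0, 1] / np.sqrt(csd.matrices[k, 0, 0].real
                                            * csd.matrices[k, 1, 1].real)
        assert abs(c.real) < 0.02
        assert c.imag == pytest.approx(1.0, abs=0.02)

    def test_single_channel_rejected(self):
        rng = np.random.default_rng(2)
        ep = pp.make_epochs(make_recording(rng.standard_normal((1, 5000)), 500.0))
        with pytest.raises(ValueError, match="single channel"):
            coupling.csd_multitaper(ep)


class TestImcohGrandAverage:
    def test_zero_lag_copy_immune(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(20 * 500)
        ep = pp.make_epochs(make_recording(np.vstack([x, 0.5 * x]), 500.0, site_split=1))
        csd = coupling.csd_multitaper(ep)
        res = coupling.imcoh_grand_average(csd, [0], [1])
        assert np.abs(res.values).max() < 1e-9

    def test_hand_computed_toy(self):
        res = coupling.imcoh_grand_average(toy_csd(0.3 + 0.4j), [0], [1])
        np.testing.assert_allclose(res.values, 0.4)

    def test_quadrature_pair_near_one(self):
        fs, f0 = 500.0, 20.0
        t = np.arange(int(20 * fs)) / fs
        a, b = np.sin(2 * np.pi * f0 * t), np.cos(2 * np.pi * f0 * t)
        ep = pp.make_epochs(make_recording(np.vstack([a, b]), fs, site_split=1))
        res = coupling.imcoh_grand_average(coupling.csd_multitaper(ep), [0], [1])
        k = np.argmin(np.abs(res.freqs - f0))
        assert res.values[k] == pytest.approx(1.0, abs=0.02)

    def test_common_mode_only_data_is_null(self):
        # channels that are scaled copies of one source: ImCoh ~ 0 everywhere
        rng = np.random.default_rng(4)
        src = rng.standard_normal(20 * 500)
        gains = np.array([1.0, -0.7, 0.4, 1.3])
        ep = pp.make_epochs(make_recording(np.outer(gains, src), 500.0, site_split=2))
        res = coupling.imcoh_grand_average(coupling.csd_multitaper(ep), [0, 1], [2, 3])
        assert np.abs(res.values).max() < 1e-6


class TestMic:
    def test_ground_truth_pattern_recovery(self, coupled_sim, coupled_epochs):
        _, _, truth = coupled_sim
        csd = coupling.csd_multitaper(coupled_epochs)
        res = coupling.mic(csd, list(range(5)), [5, 6, 7])
        band = (res.freqs >= 18.0) & (res.freqs <= 24.0)
        assert res.values[band].mean() > 2 * res.values[(res.freqs > 60)].mean()
        pat = res.seed_patterns_z[:, band].mean(axis=1)
        true_abs = np.abs(truth.mixing_cortex[:, 0])
        r = np.corrcoef(pat, (true_abs - true_abs.mean()) / true_abs.std())[0, 1]
        assert abs(r) > 0.9

    def test_instantaneous_mixing_null(self):
        rng = np.random.default_rng(5)
        src = signal.sosfiltfilt(
            signal.butter(4, [5, 60], btype="bandpass", fs=500.0, output="sos"),
            rng.standard_normal((2, 60 * 500)), axis=-1)
        mix = rng.uniform(0.5, 1.5, (5, 2))
        data = mix @ src + 0.2 * rng.standard_normal((5, 60 * 500))
        ep = pp.make_epochs(make_recording(data, 500.0, site_split=3))
        res = coupling.mic(coupling.csd_multitaper(ep), [0, 1, 2], [3, 4])
        band = (res.freqs >= 5.0) & (res.freqs <= 60.0)
        assert res.values[band].mean() < 0.1

    def test_maximisation_dominates_whitened_pairs(self, coupled_epochs):
        csd = coupling.csd_multitaper(coupled_epochs)
        seed_idx, targ_idx = [0, 1, 2, 3, 4], [5, 6, 7]
        res = coupling.mic(csd, seed_idx, targ_idx)
        s = csd.matrices
        saa = np.real(s[:, :5, :5])
        sbb = np.real(s[:, 5:, 5:])
        sab = s[:, :5, 5:]
        pa, _ = coupling._inv_sqrt_psd(saa, 1e-8)
        pb, _ = coupling._inv_sqrt_psd(sbb, 1e-8)
        d = pa @ np.imag(sab) @ pb
        # MIC (largest singular value) >= |any whitened pair entry|
        assert np.all(res.values + 1e-12 >= np.abs(d).max(axis=(1, 2)))

    def test_values_bounded_unit_interval(self, coupled_epochs):
        csd = coupling.csd_multitaper(coupled_epochs)
        res = coupling.mic(csd, list(range(5)), [5, 6, 7])
        assert np.all(res.values >= 0.0) and np.all(res.values <= 1.0 + 1e-9)


class TestVarFromCsd:
    def test_recovers_known_var_from_closed_form_spectrum(self):
        coefs = np.array([[[0.5, 0.1], [0.4, 0.3]]])
        sigma = np.array([[1.0, 0.2], [0.2, 1.5]])
        fs, nt = 200.0, 400
        freqs = np.fft.rfftfreq(nt, 1.0 / fs)
        two_sided = synth.var_csd(coefs, sigma, freqs, fs)
        one_sided = two_sided.copy()
        one_sided[1:-1] *= 2.0
        csd = coupling.CrossSpectralDensity(freqs=freqs, matrices=one_sided,
                                            sampling_rate=fs)
        model = coupling.var_from_csd(csd, order=5)
        np.testing.assert_allclose(model.coefs[0], coefs[0], atol=0.02)
        np.testing.assert_allclose(model.coefs[1:], 0.0, atol=0.02)
        np.testing.assert_allclose(model.sigma, sigma, rtol=0.05)

    def test_white_noise_csd_gives_zero_lag_coefficients(self):
        fs, nt = 200.0, 400
        freqs = np.fft.rfftfreq(nt, 1.0 / fs)
        flat = np.tile(np.eye(2, dtype=complex) * 2.0 / fs, (freqs.size, 1, 1))
        flat[1:-1] *= 2.0
        csd = coupling.CrossSpectralDensity(freqs=freqs, matrices=flat,
                                            sampling_rate=fs)
        model = coupling.var_from_csd(csd, order=10)
        assert np.abs(model.coefs).max() < 1e-10

    def test_default_order_is_60(self):
        import inspect
        assert inspect.signature(coupling.var_from_csd).parameters["order"].default == 60

    def test_estimated_gc_matches_true_var_oracle(self):
        """Whittle fit from the closed-form CSD reproduces the GC spectrum
        computed directly from the true VAR coefficients (brute-force oracle)."""
        coefs = np.array([[[0.5, 0.0], [0.5, 0.3]]])
        sigma = np.eye(2)
        fs, nt = 200.0, 800
        freqs = np.fft.rfftfreq(nt, 1.0 / fs)
        two = synth.var_csd(coefs, sigma, freqs, fs)
        one = two.copy()
        one[1:-1] *= 2.0
        csd = coupling.CrossSpectralDensity(freqs=freqs, matrices=one, sampling_rate=fs)
        fitted = coupling.var_from_csd(csd, order=20)
        grid = np.linspace(1.0, 90.0, 90)
        gc_fit = coupling.spectral_gc(fitted, grid, fs, [0], [1])
        gc_true = coupling.spectral_gc(coupling.VARModel(coefs=coefs, sigma=sigma),
                                       grid, fs, [0], [1])
        assert np.abs(gc_fit - gc_true).max() < 0.02 * np.abs(gc_true).max()


class TestTrgc:
    def _var_csd_epochs(self, seed=0, n=60_000):
        coefs = np.zeros((2, 2, 2))
        coefs[0] = [[0.5, 0.0], [0.4, 0.4]]
        coefs[1] = [[-0.2, 0.0], [0.2, 0.1]]
        x = synth.simulate_var(coefs, np.eye(2), n, seed=seed)
        ep = pp.make_epochs(make_recording(x, 250.0, site_split=1))
        return coupling.csd_multitaper(ep)

    def test_one_way_coupling_positive(self):
        csd = self._var_csd_epochs()
        res = coupling.trgc(csd, [0], [1], order=30, band=(3.0, 50.0))
        assert res.values.mean() > 0.0
        assert res.method == "trgc"

    def test_antisymmetry_exact(self):
        csd = self._var_csd_epochs(seed=1)
        fwd = coupling.trgc(csd, [0], [1], order=30, band=(3.0, 50.0))
        rev = coupling.trgc(csd, [1], [0], order=30, band=(3.0, 50.0))
        assert np.abs(fwd.values + rev.values).max() < 1e-10

    def test_time_reversal_zeroes_real_csd(self):
        # instantaneous mixing has a purely real CSD; TRGC must vanish exactly
        fs, nt = 250.0, 500
        freqs = np.fft.rfftfreq(nt, 1.0 / fs)
        sos = signal.butter(4, [3 / 125.0, 60 / 125.0], btype="bandpass")
        _, h = signal.freqz(*signal.butter(4, [3 / 125.0, 60 / 125.0], btype="bandpass"),
                            worN=freqs, fs=fs)
        ps = np.abs(h) ** 2 + 0.01
        mats = np.zeros((freqs.size, 2, 2), dtype=complex)
        mats[:, 0, 0] = ps + 0.02
        mats[:, 1, 1] = 0.6 * ps + 0.02
        mats[:, 0, 1] = mats[:, 1, 0] = 0.7 * ps
        csd = coupling.CrossSpectralDensity(freqs=freqs, matrices=mats, sampling_rate=fs)
        res = coupling.trgc(csd, [0], [1], order=20, band=(3.0, 50.0))
        net = coupling.trgc(csd, [0], [1], order=20, band=(3.0, 50.0),
                            time_reversed=False)
        assert np.abs(res.values).max() < 1e-10
        assert np.abs(net.values).max() > 0.01  # the uncorrected net score is not zero


class TestAverageSegments:
    def _spec(self, values):
        return coupling.CouplingSpectrum(freqs=np.array([1.0, 2.0]),
                                         values=np.asarray(values), method="imcoh")

    def test_identical_segments(self):
        avg = coupling.average_segments([self._spec([0.2, 0.4])] * 3)
        np.testing.assert_allclose(avg.values, [0.2, 0.4])
        assert avg.segment_count == 3

    def test_mean_arithmetic(self):
        avg = coupling.average_segments([self._spec([0.2, 0.0]), self._spec([0.4, 1.0])])
        np.testing.assert_allclose(avg.values, [0.3, 0.5])

    def test_mismatched_grids_rejected(self):
        other = coupling.CouplingSpectrum(freqs=np.array([1.0, 3.0]),
                                          values=np.array([0.1, 0.2]), method="imcoh")
        with pytest.raises(ValueError):
            coupling.average_segments([self._spec([0.1, 0.2]), other])

    def test_bootstrap_csds_match_direct_average(self):
        rng = np.random.default_rng(9)
        ep = pp.make_epochs(make_recording(rng.standard_normal((2, 10 * 500)),
                                           500.0, site_split=1))
        segs = pp.bootstrap_segments(ep, n_segments=4, epochs_per_segment=3, seed=0)
        csds = coupling.bootstrap_csds(ep, segs)
        coeffs, freqs = spectral.taper_fft(ep.data, 500.0, 5.0)
        p = coupling.epoch_cross_products(coeffs, freqs, 500.0, ep.data.shape[-1])
        want = p[segs.segments[0]].mean(axis=0)
        np.testing.assert_allclose(csds[0].matrices, want, atol=1e-12)
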