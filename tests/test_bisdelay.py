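"""Bispectral time-delay estimation: oracles, recovery, binning rules."""

import numpy as np
import pytest

from ctxstn import bisdelay, synth
from ctxstn import preprocess as pp
from tests.conftest import make_recording


def epochs_from_pair(a, b, fs=1000.0):
    return pp.make_epochs(make_recording(np.vstack([a, b]), fs, site_split=1))


def delayed_pair(seed=2, delay=25, dur=30.0, snr=np.inf, band=(10.0, 45.0)):
    cfg = synth.SimConfig(sampling_rate=1000.0, duration=dur, source_band=band,
                          coupling_delay=float(delay), snr=snr,
                          line_noise_amplitude=0.0, n_cortex_channels=1,
                          n_stn_channels=1, seed=seed)
    src = synth.simulate_sources(cfg)
    _, truth = synth.couple_and_mix(src, cfg)
    return truth.extras["seed_source"], truth.extras["target_source"]


class TestFourierCoefficients:
    def test_zero_input_zero_coefficients(self):
        ep = epochs_from_pair(np.zeros(4000), np.zeros(4000))
        coeffs, _ = bisdelay.fourier_coefficients(ep)
        assert np.abs(coeffs).max() == 0.0

    def test_windowed_impulse_flat_magnitude(self):
        a = np.zeros(4000)
        a[0] = 1.0
        a[2000] = 1.0  # impulse at the start of each 2 s epoch
        ep = epochs_from_pair(a, a)
        coeffs, _ = bisdelay.fourier_coefficients(ep)
        from scipy.signal.windows import hamming
        w0 = hamming(2000, sym=False)[0]
        mags = np.abs(coeffs[0, 0])
        np.testing.assert_allclose(mags, w0, rtol=1e-9)

    def test_grid_2s_1000hz_4001_points(self):
        ep = epochs_from_pair(np.random.default_rng(0).standard_normal(4000),
                              np.zeros(4000))
        assert ep.data.shape[-1] == 2000
        coeffs, freqs = bisdelay.fourier_coefficients(ep)
        assert coeffs.shape[-1] == 4001 and freqs.size == 4001

    def test_wrong_rate_rejected(self):
        ep = epochs_from_pair(np.zeros(2000), np.zeros(2000), fs=500.0)
        with pytest.raises(ValueError, match="1000"):
            bisdelay.fourier_coefficients(ep)


class TestCrossBispectrum:
    def test_matches_brute_force_triple_products(self):
        """3 epochs x 16 samples: estimator equals explicit triple-loop sums."""
        rng = np.random.default_rng(0)
        n = 16
        x = rng.standard_normal((3, n))
        y = rng.standard_normal((3, n))
        cx = np.fft.fft(x, axis=-1)
        cy = np.fft.fft(y, axis=-1)
        freqs = np.fft.fftfreq(n, 1.0 / 16.0)  # fs = 16 -> 1 Hz bins
        for kind in ("xxx", "yxx", "xyx", "xxy"):
            b, meta = bisdelay.cross_bispectrum(cx, cy, freqs, band=(1.0, 4.0),
                                                kind=kind)
            idx = meta["band_indices"]
            chans = {"x": cx, "y": cy}
            brute = np.zeros((idx.size, idx.size), dtype=complex)
            for i, k1 in enumerate(idx):
                for j, k2 in enumerate(idx):
                    acc = 0.0
                    for e in range(3):
                        acc += (chans[kind[0]][e, k1] * chans[kind[1]][e, k2]
                                * np.conj(chans[kind[2]][e, k1 + k2]))
                    brute[i, j] = acc / 3.0
            assert np.abs(b - brute).max() < 1e-10

    def test_auto_bispectrum_symmetric(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((4, 32))
        cx = np.fft.fft(x, axis=-1)
        freqs = np.fft.fftfreq(32, 1.0 / 32.0)
        b, _ = bisdelay.cross_bispectrum(cx, cx, freqs, band=(1.0, 8.0), kind="xxx")
        np.testing.assert_allclose(b, b.T, atol=1e-12)

    def test_gaussian_suppression_vs_skewed(self):
        """Gaussian sources: |B| well below equally powered skewed sources."""
        cfg_g = synth.SimConfig(sampling_rate=1000.0, duration=240.0,
                                source_band=(10.0, 45.0), nongaussianity=0.0, seed=3)
        cfg_s = synth.SimConfig(sampling_rate=1000.0, duration=240.0,
                                source_band=(10.0, 45.0), nongaussianity=1.0, seed=3)
        mags = {}
        for name, cfg in (("gauss", cfg_g), ("skew", cfg_s)):
            src = synth.simulate_sources(cfg)[0]
            ep = epochs_from_pair(src, src)
            coeffs, freqs = bisdelay.fourier_coefficients(ep)
            # evaluate over the sources' own band, where the skewed
            # bispectrum has support; outside it both are pure noise
            b, _ = bisdelay.cross_bispectrum(coeffs[:, 0], coeffs[:, 0], freqs,
                                             band=(10.0, 45.0), kind="xxx")
            mags[name] = np.abs(b).mean()
        assert mags["gauss"] < 0.2 * mags["skew"]

    def test_too_few_epochs_rejected(self):
        c = np.zeros((1, 64), dtype=complex)
        freqs = np.fft.fftfreq(64, 1.0 / 64.0)
        with pytest.raises(ValueError, match="2 epochs"):
            bisdelay.cross_bispectrum(c, c, freqs, band=(1.0, 8.0))

    def test_band_outside_support_rejected(self):
        c = np.zeros((3, 64), dtype=complex)
        freqs = np.fft.fftfreq(64, 1.0 / 64.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bisdelay.cross_bispectrum(c, c, freqs, band=(1.0, 30.0))


class TestDelayStrength:
    def test_identical_signals_zero_delay(self):
        a, _ = delayed_pair(seed=5, delay=0)
        ep = epochs_from_pair(a, a.copy())
        coeffs, freqs = bisdelay.fourier_coefficients(ep)
        est = bisdelay.delay_strength(coeffs[:, 0], coeffs[:, 1], freqs)
        assert est.tau == 0.0

    def test_25ms_delay_recovered_with_xcorr_agreement(self):
        from scipy.signal import correlate, correlation_lags
        a, b = delayed_pair(seed=2, delay=25)
        ep = epochs_from_pair(a, b)
        coeffs, freqs = bisdelay.fourier_coefficients(ep)
        est = bisdelay.delay_strength(coeffs[:, 0], coeffs[:, 1], freqs)
        lags = correlation_lags(b.size, a.size)
        xcorr_lag = lags[np.argmax(correlate(b, a))]
        assert abs(est.tau - 25.0) <= 1.0
        assert abs(est.tau - xcorr_lag) <= 1.0

    def test_role_swap_negates_tau(self):
        a, b = delayed_pair(seed=7, delay=15)
        ep = epochs_from_pair(a, b)
        coeffs, freqs = bisdelay.fourier_coefficients(ep)
        fwd = bisdelay.delay_strength(coeffs[:, 0], coeffs[:, 1], freqs)
        rev = bisdelay.delay_strength(coeffs[:, 1], coeffs[:, 0], freqs)
        assert abs(fwd.tau + rev.tau) <= 1.0

    def test_strength_is_real_with_tiny_imaginary_residue(self):
        a, b = delayed_pair(seed=8, delay=10, dur=10.0)
        ep = epochs_from_pair(a, b)
        coeffs, freqs = bisdelay.fourier_coefficients(ep)
        b_auto, meta = bisdelay.cross_bispectrum(coeffs[:, 0], coeffs[:, 1], freqs,
                                                 kind="xxx")
        b_cross, _ = bisdelay.cross_bispectrum(coeffs[:, 0], coeffs[:, 1], freqs,
                                               kind="yxx")
        q = b_auto * np.conj(b_cross)
        q /= np.abs(q)
        g = q.sum(axis=-1)
        idx = meta["band_indices"]
        spec = np.zeros(4001, dtype=complex)
        spec[idx] = g
        spec[4001 - idx] += np.conj(g)
        s = np.fft.fft(spec)
        assert np.abs(s.imag).max() < 1e-10 * np.abs(s.real).max()

    def test_all_zero_bispectrum_rejected(self):
        ep = epochs_from_pair(np.zeros(4000), np.zeros(4000))
        coeffs, freqs = bisdelay.fourier_coefficients(ep)
        with pytest.raises(ValueError, match="all-zero"):
            bisdelay.delay_strength(coeffs[:, 0], coeffs[:, 1], freqs)


class TestBootstrapDelay:
    def test_recovery_with_confidence_interval(self):
        cfg = synth.SimConfig(sampling_rate=1000.0, duration=60.0,
                              source_band=(10.0, 45.0), coupling_delay=25.0,
                              snr=10.0, line_noise_amplitude=0.0,
                              n_cortex_channels=1, n_stn_channels=1, seed=12)
        src = synth.simulate_sources(cfg)
        rec, _ = synth.couple_and_mix(src, cfg)
        ep = pp.make_epochs(rec)
        segs = pp.bootstrap_segments(ep, n_segments=100, seed=3)
        coeffs, freqs = bisdelay.fourier_coefficients(ep)
        est = bisdelay.bootstrap_delay(coeffs[:, 0], coeffs[:, 1], freqs, segs)
        assert est.valid is True
        assert est.ci80 is not None and 0.0 < est.ci80[0] <= est.ci80[1] < 50.0
        assert abs(est.tau - 25.0) <= 2.0
        assert abs(est.segment_tau_mean - 25.0) <= 2.0

    def test_independent_noise_mostly_invalid(self):
        rng = np.random.default_rng(13)
        invalid = 0
        for k in range(6):
            a = rng.standard_normal(30_000)
            b = rng.standard_normal(30_000)
            ep = epochs_from_pair(a, b)
            segs = pp.bootstrap_segments(ep, n_segments=60, seed=k)
            coeffs, freqs = bisdelay.fourier_coefficients(ep)
            est = bisdelay.bootstrap_delay(coeffs[:, 0], coeffs[:, 1], freqs, segs)
            invalid += int(not est.valid)
        assert invalid >= 4  # the confidence screen rejects most null connections

    def test_degenerate_identical_taus(self):
        a, b = delayed_pair(seed=2, delay=25, dur=20.0)
        ep = epochs_from_pair(a, b)
        # every segment resamples the same single epoch -> identical taus
        segs = pp.SegmentSet(segments=np.zeros((10, 30), dtype=int), seed=0,
                             coverage=0.1)
        coeffs, freqs = bisdelay.fourier_coefficients(ep)
        est = bisdelay.bootstrap_delay(coeffs[:, 0], coeffs[:, 1], freqs, segs)
        assert est.ci80[0] == est.ci80[1] == est.segment_taus[0]
        assert est.valid == (not est.ci80[0] <= 0.0 <= est.ci80[1])

    def test_too_few_segments_rejected(self):
        a, b = delayed_pair(seed=2, delay=25, dur=10.0)
        ep = epochs_from_pair(a, b)
        segs = pp.SegmentSet(segments=np.zeros((1, 30), dtype=int), seed=0,
                             coverage=0.2)
        coeffs, freqs = bisdelay.fourier_coefficients(ep)
        with pytest.raises(ValueError, match="2 segments"):
            bisdelay.bootstrap_delay(coeffs[:, 0], coeffs[:, 1], freqs, segs)


class TestPeakBinning:
    def _estimate(self, peak_lags, heights=None, baseline=0.1):
        lags = np.arange(-2000.0, 2001.0)
        s = np.zeros(lags.size)
        s[lags == 0.0] = baseline
        heights = heights or [1.0] * len(peak_lags)
        for lag, h in zip(peak_lags, heights):
            s[np.flatnonzero(lags == float(lag))[0]] = h
        return bisdelay.DelayEstimate(lags=lags, strength=s, tau=0.0)

    def test_single_peak_first_bin(self):
        est = bisdelay.peak_binning(self._estimate([5]))
        assert est.peaks == [5.0]
        assert est.bin_percentages == {"1-9": 100.0}

    def test_two_peaks_split_bins(self):
        est = bisdelay.peak_binning(self._estimate([5, 30]))
        assert est.bin_percentages == {"1-9": 50.0, "30-39": 50.0}

    def test_minimum_separation_rule(self):
        est = bisdelay.peak_binning(self._estimate([20, 23], heights=[1.0, 0.8]))
        assert est.peaks == [20.0]

    def test_peaks_below_baseline_ignored(self):
        est = bisdelay.peak_binning(self._estimate([15], heights=[0.05], baseline=0.1))
        assert est.peaks == []
        assert est.bin_percentages is None

    def test_percentages_sum_to_100(self):
        est = bisdelay.peak_binning(self._estimate([5, 17, 30, 44, 91]))
        assert sum(est.bin_percentages.values()) == pytest.approx(100.0)
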