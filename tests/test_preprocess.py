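"""Filtering, epoching, referencing, artifact handling, bootstrap segments."""

import numpy as np
import pytest
from scipy import signal

from ctxstn import preprocess as pp
from ctxstn import synth
from tests.conftest import make_recording


def sine_recording(freqs, fs=500.0, dur=10.0, amps=None):
    t = np.arange(int(fs * dur)) / fs
    amps = amps or [1.0] * len(freqs)
    data = sum(a * np.sin(2 * np.pi * f * t) for f, a in zip(freqs, amps))
    return make_recording(data[None, :], fs)


def peak_power(x, fs, freq, width=1.0):
    f, p = signal.periodogram(x, fs=fs)
    return p[np.abs(f - freq) <= width].sum()


class TestNotchFilter:
    def test_line_component_removed(self):
        rec = sine_recording([50.0])
        out = pp.notch_filter(rec, 50.0)
        mid = slice(500, -500)  # steady state, away from filtfilt edge transients
        assert np.std(out.data[0, mid]) < 0.01 * np.std(rec.data[0, mid])

    def test_passband_preserved(self):
        rec = sine_recording([20.0])
        out = pp.notch_filter(rec, 50.0)
        mid = slice(500, -500)
        assert np.std(out.data[0, mid]) == pytest.approx(np.std(rec.data[0, mid]), rel=0.01)

    def test_harmonics_attenuated_40db(self):
        rec = sine_recording([50.0, 100.0, 150.0], fs=500.0, dur=20.0)
        out = pp.notch_filter(rec, 50.0)
        mid = slice(2000, -2000)  # steady state only
        for f0 in (50.0, 100.0, 150.0):
            before = peak_power(rec.data[0, mid], 500.0, f0)
            after = peak_power(out.data[0, mid], 500.0, f0)
            assert 10 * np.log10(before / after) >= 40.0

    def test_line_freq_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            pp.notch_filter(sine_recording([10.0], fs=80.0), 50.0)


class TestBandpassFilter:
    def test_dc_removed(self):
        rec = make_recording(np.full((1, 5000), 7.3), 500.0)
        out = pp.bandpass_filter(rec, 3.0, 150.0)
        assert np.abs(out.data.mean()) < 0.01

    def test_band_interior_preserved(self):
        rec = sine_recording([20.0])
        out = pp.bandpass_filter(rec, 3.0, 150.0)
        mid = slice(500, -500)
        assert np.std(out.data[0, mid]) == pytest.approx(np.std(rec.data[0, mid]), rel=0.01)

    def test_out_of_band_power_below_1pct(self):
        rng = np.random.default_rng(0)
        rec = make_recording(rng.standard_normal((1, 200_000)), 1000.0)
        out = pp.bandpass_filter(rec, 3.0, 150.0)
        f, p = signal.periodogram(out.data[0], fs=1000.0)
        stop = (f < 1.5) | (f > 300.0)
        assert p[stop].sum() < 0.01 * p.sum()

    def test_idempotence_within_1db(self):
        rng = np.random.default_rng(1)
        rec = make_recording(rng.standard_normal((1, 100_000)), 1000.0)
        once = pp.bandpass_filter(rec, 3.0, 150.0)
        twice = pp.bandpass_filter(once, 3.0, 150.0)
        f, p1 = signal.periodogram(once.data[0], fs=1000.0)
        _, p2 = signal.periodogram(twice.data[0], fs=1000.0)
        band = (f >= 6.0) & (f <= 75.0)
        ratio_db = 10 * np.log10(p2[band].sum() / p1[band].sum())
        assert abs(ratio_db) < 1.0

    def test_hi_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            pp.bandpass_filter(sine_recording([10.0], fs=300.0), 3.0, 150.0)


class TestEpochsAndResample:
    def test_epoch_count_floor(self):
        rec = make_recording(np.zeros((1, int(61 * 4000))), 4000.0)
        ep = pp.make_epochs(rec, 2.0)
        assert ep.n_epochs == 30

    def test_resample_sample_count(self):
        rec = make_recording(np.zeros((1, 8000 * 4)), 4000.0)
        ep = pp.resample(pp.make_epochs(rec, 2.0), 500.0)
        assert ep.data.shape[-1] == 1000
        ep2 = pp.resample(pp.make_epochs(rec, 2.0), 1000.0)
        assert ep2.data.shape[-1] == 2000

    def test_resampled_sine_matches_analytic(self):
        fs = 4000.0
        t = np.arange(int(4 * fs)) / fs
        rec = make_recording(np.sin(2 * np.pi * 10.0 * t)[None, :], fs)
        ep = pp.resample(pp.make_epochs(rec, 2.0), 1000.0)
        t2 = np.arange(2000) / 1000.0
        want = np.sin(2 * np.pi * 10.0 * t2)
        err = np.abs(ep.data[0, 0, 100:-100] - want[100:-100]).max()
        assert err < 1e-3

    def test_too_short_recording_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            pp.make_epochs(make_recording(np.zeros((1, 100)), 1000.0), 2.0)


class TestArtifactRejection:
    def test_identical_epochs_kept(self):
        data = np.tile(np.sin(np.linspace(0, 20 * np.pi, 1000)), (1, 10))
        ep = pp.make_epochs(make_recording(data, 500.0), 2.0)
        out, log = pp.reject_artifact_epochs(ep, 4.0)
        assert out.kept_mask.all() and log["n_rejected"] == 0

    def test_constructed_outlier_rejected(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((1, 30 * 1000))
        data[0, 7 * 1000: 7 * 1000 + 50] += 100.0
        ep = pp.make_epochs(make_recording(data, 500.0), 2.0)
        out, log = pp.reject_artifact_epochs(ep, 4.0)
        # 2 s epochs at 500 Hz = 1000 samples each; the spike sits in epoch 7
        assert log["rejected_indices"] == [7]
        assert not out.kept_mask[7] and out.kept_mask.sum() == 29

    def test_infinite_threshold_keeps_all(self):
        rng = np.random.default_rng(1)
        ep = pp.make_epochs(make_recording(rng.standard_normal((2, 10_000)), 500.0))
        out, _ = pp.reject_artifact_epochs(ep, np.inf)
        assert out.kept_mask.all()


class TestParrm:
    def test_non_dbs_condition_untouched(self):
        rec = make_recording(np.random.default_rng(0).standard_normal((1, 8000)),
                             4000.0, condition="off")
        assert pp.parrm_remove(rec, 130.0) is rec

    def test_artifact_free_input_unchanged(self):
        rng = np.random.default_rng(2)
        rec = make_recording(5 * rng.standard_normal((1, 40_000)), 4000.0,
                             condition="dbs")
        out = pp.parrm_remove(rec, 130.0)
        dev = np.abs(out.data - rec.data).max()
        assert dev < 0.01 * np.std(rec.data)

    def test_pure_train_removed(self):
        rec = make_recording(np.zeros((1, 80_000)), 4000.0, condition="dbs")
        train = synth.add_dbs_artifact(rec, 130.0, 60.0, 200.0, seed=1)
        out = pp.parrm_remove(train, 130.0)
        assert np.std(out.data) < 0.05 * np.std(train.data)

    def test_neural_band_power_preserved(self):
        fs, dur = 4000.0, 20.0
        t = np.arange(int(fs * dur)) / fs
        rng = np.random.default_rng(3)
        neural = 20 * np.sin(2 * np.pi * 20.0 * t) + rng.standard_normal(t.size)
        clean = make_recording(neural[None, :].copy(), fs, condition="dbs")
        dirty = synth.add_dbs_artifact(clean, 130.0, 60.0, 200.0, seed=4)
        out = pp.parrm_remove(dirty, 130.0)

        def band_power(x):
            f, p = signal.welch(x, fs, nperseg=int(4 * fs))
            return p[(f >= 10.0) & (f <= 35.0)].sum()

        db = 10 * np.log10(band_power(out.data[0]) / band_power(clean.data[0]))
        assert abs(db) < 1.0


class TestBipolarReference:
    def _rec(self, n_cortex=6, n_stn=3, fs=500.0, n=5000):
        rng = np.random.default_rng(0)
        return make_recording(rng.standard_normal((n_cortex + n_stn, n)), fs,
                              site_split=n_cortex)

    def test_common_mode_rejected(self):
        common = np.sin(np.linspace(0, 40 * np.pi, 5000))
        data = np.tile(common, (6, 1))
        rec = make_recording(data, 500.0, site_split=4)
        out = pp.bipolar_reference(rec)
        assert np.abs(out.data).max() < 1e-12

    def test_adjacent_count(self):
        out = pp.bipolar_reference(self._rec(6, 3))
        cortex = [c for c in out.channel_info if c.site == "cortex"]
        stn = [c for c in out.channel_info if c.site == "stn"]
        assert len(cortex) == 5 and len(stn) == 2
        assert all(c.montage == "bipolar" for c in out.channel_info)
        assert cortex[0].constituents == ("ECOG_1", "ECOG_2")

    def test_analytic_difference(self):
        t = np.linspace(0, 2, 1000)
        s1, s2 = np.sin(2 * np.pi * 5 * t), np.sin(2 * np.pi * 9 * t)
        rec = make_recording(np.vstack([s1, s2, s1, s2]), 500.0, site_split=2)
        out = pp.bipolar_reference(rec)
        np.testing.assert_allclose(out.data[0], s1 - s2, atol=1e-12)

    def test_single_contact_site_rejected(self):
        with pytest.raises(ValueError, match="single contact"):
            pp.bipolar_reference(self._rec(6, 1))


class TestStimContactExclusion:
    def test_empty_list_unchanged(self):
        rec = make_recording(np.zeros((4, 100)), 500.0, site_split=2)
        assert pp.exclude_stim_contacts(rec, []) is rec

    def test_counts_and_unknown_names(self):
        rec = make_recording(np.zeros((10, 100)), 500.0, site_split=2)
        out = pp.exclude_stim_contacts(rec, ["LFP_2", "LFP_5"])
        assert out.n_channels == 8
        with pytest.raises(ValueError, match="unknown"):
            pp.exclude_stim_contacts(rec, ["LFP_99"])

    def test_levodopa_pair_retains_contacts(self):
        a = make_recording(np.zeros((6, 100)), 500.0, site_split=2, condition="off")
        b = make_recording(np.zeros((6, 100)), 500.0, site_split=2, condition="levodopa")
        ha, hb = pp.harmonize_stim_contacts(a, b, ["LFP_1"])
        assert ha.n_channels == 6 and hb.n_channels == 6
        c = make_recording(np.zeros((6, 100)), 500.0, site_split=2, condition="dbs")
        ha, hc = pp.harmonize_stim_contacts(a, c, ["LFP_1"])
        assert ha.n_channels == 5 and hc.n_channels == 5


class TestBootstrapSegments:
    def _epochs(self, n_epochs=40):
        return pp.make_epochs(
            make_recording(np.random.default_rng(0).standard_normal(
                (1, n_epochs * 1000)), 500.0))

    def test_shapes_and_counts(self):
        segs = pp.bootstrap_segments(self._epochs(), 200, 30, seed=0)
        assert segs.segments.shape == (200, 30)
        segs400 = pp.bootstrap_segments(self._epochs(), 400, 30, seed=0)
        assert segs400.n_segments == 400

    def test_seed_reproducibility(self):
        ep = self._epochs()
        a = pp.bootstrap_segments(ep, 50, seed=5)
        b = pp.bootstrap_segments(ep, 50, seed=5)
        np.testing.assert_array_equal(a.segments, b.segments)

    def test_single_kept_epoch_degenerate(self):
        ep = self._epochs(5)
        ep.kept_mask[:] = False
        ep.kept_mask[2] = True
        segs = pp.bootstrap_segments(ep, 10, 30, seed=1)
        assert (segs.segments == 2).all()
        assert segs.coverage == 1.0

    def test_no_kept_epochs_rejected(self):
        ep = self._epochs(5)
        ep.kept_mask[:] = False
        with pytest.raises(ValueError):
            pp.bootstrap_segments(ep, 10, seed=0)

    def test_only_kept_epochs_drawn(self):
        ep = self._epochs(20)
        ep.kept_mask[::2] = False
        segs = pp.bootstrap_segments(ep, 50, seed=3)
        assert np.isin(segs.segments, np.flatnonzero(ep.kept_mask)).all()
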