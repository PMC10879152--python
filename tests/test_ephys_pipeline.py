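"""Preprocessing, spike detection, PSTH and the comparison statistics."""

import numpy as np
import pytest

from somatosim import ephys_pipeline as ep
from somatosim import stim_encoding as se
from somatosim import synthetic_ephys as sy

FS = 25000.0


def as_recording(x, fs=FS):
    x = np.atleast_2d(np.asarray(x, float))
    geom = sy.ProbeGeometry(x.shape[0], "linear", 100.0)
    return sy.MultichannelRecording(fs, x, geom)


def sine(freq, duration=2.0, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


def rms(x):
    return np.sqrt(np.mean(np.square(x)))


def interior(x, fs=FS):
    n = int(0.5 * fs)
    return x[n:-n]


class TestRobustSigma:
    def test_gaussian_identity(self, rng):
        est = ep.robust_sigma(rng.standard_normal(10 ** 6))
        assert est.sigma == pytest.approx(1.0, abs=0.01)

    def test_direct_formula(self):
        assert ep.robust_sigma(np.array([-2.0, 2.0, -2.0, 2.0])).sigma == \
            pytest.approx(2 / 0.6745)
        assert ep.robust_sigma(np.zeros(100)).sigma == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ep.robust_sigma(np.empty(0))


class TestFilters:
    @pytest.mark.parametrize("freq,max_gain", [(50, 0.03), (150, 0.03),
                                               (100, 0.03)])
    def test_comb_notch_attenuates_harmonics(self, freq, max_gain):
        out = ep.comb_notch(as_recording(sine(freq))).voltages[0]
        assert rms(interior(out)) <= max_gain * rms(interior(sine(freq)))

    @pytest.mark.parametrize("freq", [35, 75])
    def test_comb_notch_passband_ripple(self, freq):
        out = ep.comb_notch(as_recording(sine(freq))).voltages[0]
        gain = rms(interior(out)) / rms(interior(sine(freq)))
        assert abs(gain - 1.0) <= 0.12

    def test_highpass_rejects_dc_and_low_freq(self):
        const = as_recording(np.full(int(2 * FS), 5.0))
        out = ep.butter_highpass(const).voltages[0]
        assert np.abs(out).mean() <= 1e-6 * 5.0
        slow = ep.butter_highpass(as_recording(sine(1.0))).voltages[0]
        assert rms(interior(slow)) <= 0.01 * rms(interior(sine(1.0)))

    def test_highpass_passes_100hz(self):
        out = ep.butter_highpass(as_recording(sine(100.0))).voltages[0]
        gain = rms(interior(out)) / rms(interior(sine(100.0)))
        assert abs(gain - 1.0) <= 0.05

    @pytest.mark.parametrize("freq,band,lo,hi", [
        (100, ep.LFP_BAND_HZ, 0.95, 1.05),
        (1000, ep.LFP_BAND_HZ, 0.0, 0.05),
        (2000, ep.SPIKE_BAND_HZ, 0.95, 1.05),
    ])
    def test_band_extract_gains(self, freq, band, lo, hi):
        out = ep.band_extract(as_recording(sine(freq)), band).voltages[0]
        gain = rms(interior(out)) / rms(interior(sine(freq)))
        assert lo <= gain <= hi

    def test_filters_preserve_shape_and_finiteness(self, rng):
        rec = as_recording(rng.standard_normal((3, int(FS))))
        for out in (ep.comb_notch(rec), ep.butter_highpass(rec),
                    ep.band_extract(rec, ep.LFP_BAND_HZ)):
            assert out.voltages.shape == rec.voltages.shape
            assert np.all(np.isfinite(out.voltages))

    def test_invalid_band_rejected(self, rng):
        rec = as_recording(rng.standard_normal(1000))
        with pytest.raises(ValueError):
            ep.band_extract(rec, (300.0, 30.0))


class TestBlankArtifacts:
    def test_transient_blanked_with_padding(self, rng):
        x = rng.standard_normal(int(FS))
        i0 = int(0.5 * FS)
        x[i0:i0 + 25] += 25.0
        rec = as_recording(x)
        out, mask = ep.blank_artifacts(rec, multiple=15.0, pad_ms=10.0)
        pad = int(0.010 * FS)
        assert np.all(out.voltages[0, i0 - pad + 1:i0 + 25 + pad - 1] == 0)
        assert mask.sum() >= 25 + 2 * pad - 2

    def test_clean_signal_unchanged(self, rng):
        rec = as_recording(rng.standard_normal(int(FS)))
        out, mask = ep.blank_artifacts(rec)
        assert not mask.any()
        np.testing.assert_array_equal(out.voltages, rec.voltages)


class TestDetectSpikes:
    def test_polarity(self):
        x = 0.1 * np.cos(np.arange(int(FS)))  # deterministic floor
        x[::2500] = 5.0  # positive-going events only
        det = ep.detect_spikes(as_recording(x), multiple=3.0,
                               polarity="negative")
        assert det.total() == 0
        det_pos = ep.detect_spikes(as_recording(x), multiple=3.0,
                                   polarity="positive")
        assert det_pos.total() == 10

    def test_dead_time_enforced(self, rng):
        x = rng.standard_normal(int(FS))
        det = ep.detect_spikes(as_recording(x), multiple=1.0,
                               dead_time_s=2e-3)
        isi = np.diff(det.spike_times[0])
        assert isi.min() >= 2e-3 - 1e-9

    def test_noise_false_positive_rate_near_rice_bound(self, rng):
        """Threshold crossings of band-limited Gaussian noise stay within
        3x the Rice level-crossing expectation."""
        from scipy import signal as sps
        sos = sps.butter(3, (800, 5000), "bandpass", fs=FS, output="sos")
        x = sps.sosfiltfilt(sos, rng.standard_normal(int(30 * FS)))
        det = ep.detect_spikes(as_recording(x), multiple=4.0,
                               dead_time_s=1e-3)
        f1, f2 = 800.0, 5000.0
        f_zero = 2 * np.sqrt((f2 ** 3 - f1 ** 3) / (3 * (f2 - f1)))
        rice = 0.5 * f_zero * np.exp(-(4.0 ** 2) / 2)
        rate = det.total() / 30.0
        assert rate <= 3 * rice

    def test_recall_precision_on_ground_truth(self):
        from somatosim.experiment import evaluate_spike_detection
        recall, precision = evaluate_spike_detection(seed=3)
        assert recall >= 0.95
        assert precision >= 0.9


class TestBinningAndPsth:
    def test_fd_bin_width_formula(self):
        samples = np.array([0.0, 0.0, 0.0, 0.0, 1.0, 1.0, 1.0, 1.0])
        assert ep.fd_bin_width(samples) == pytest.approx(1.0)

    def test_fd_degenerate_iqr(self):
        with pytest.raises(ep.DegenerateBinWidthError):
            ep.fd_bin_width(np.ones(10))

    def test_fd_width_plausible_for_spike_data(self, rng):
        spikes = rng.uniform(0, 2.0, 30000)  # ~90 trials of dense MUA
        width = ep.fd_bin_width(spikes)
        assert 0.005 <= width <= 0.1

    def test_psth_rate_of_homogeneous_poisson(self, rng):
        rate, n_trials, t = 40.0, 50, 2.0
        spikes = []
        for k in range(n_trials):
            n = rng.poisson(rate * t)
            spikes.append(np.sort(rng.uniform(0, t, n)) + 10.0 * k)
        psth, raster = ep.build_psth(np.concatenate(spikes),
                                     np.arange(n_trials) * 10.0, (0, t),
                                     0.05)
        se_mc = np.sqrt(rate / (n_trials * 0.05 * psth.rate_per_bin.size))
        assert abs(psth.rate_per_bin.mean() - rate) < 3 * se_mc
        assert len(raster) == n_trials

    def test_psth_single_spike_rate(self):
        psth, _ = ep.build_psth(np.array([0.105]), np.array([0.0, 1.0]),
                                (0, 1.0), 0.01)
        expected = 1.0 / (2 * 0.01)
        assert psth.rate_per_bin.max() == pytest.approx(expected)
        assert psth.rate_per_bin.sum() == pytest.approx(expected)

    def test_psth_empty(self):
        psth, _ = ep.build_psth(np.empty(0), np.array([0.0]), (0, 1.0), 0.1)
        assert np.all(psth.rate_per_bin == 0)


class TestSummedNormalizedActivity:
    def test_identical_psths_all_one(self):
        p = np.array([1.0, 2.0, 3.0])
        out = ep.summed_normalized_activity({"a": p, "b": p.copy()})
        assert out == {"a": 1.0, "b": 1.0}

    def test_flat_beats_peaked(self):
        n = 10
        out = ep.summed_normalized_activity(
            {"flat": np.full(n, 5.0),
             "peaked": np.r_[5.0, np.zeros(n - 1)]})
        assert out["flat"] == 1.0
        assert out["peaked"] == pytest.approx(1.0 / n)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            ep.summed_normalized_activity({"a": np.zeros(3),
                                           "b": np.ones(3)})


class TestXcorr:
    def test_identity_peak(self):
        a = np.array([0.0, 1.0, 3.0, 1.0, 0.0])
        res = ep.xcorr_profiles(a, a, bin_width=0.01)
        assert res.peak == pytest.approx(1.0)
        assert res.peak_lag_s == 0.0

    def test_shift_recovered(self, rng):
        a = rng.standard_normal(200)
        b = np.roll(a, 3)
        res = ep.xcorr_profiles(a, b, bin_width=0.01)
        assert res.peak_lag_s == pytest.approx(-0.03)
        assert res.peak > 0.9

    def test_independent_noise_small_peak(self, rng):
        peaks = []
        for _ in range(40):
            res = ep.xcorr_profiles(rng.standard_normal(1000),
                                    rng.standard_normal(1000),
                                    max_lag_s=0.0, bin_width=0.01)
            peaks.append(abs(res.peak))
        assert np.quantile(peaks, 0.95) <= 0.15

    def test_mismatched_grids_rejected(self):
        a = se.RateProfile(np.arange(11) * 0.01, np.ones(10))
        b = se.RateProfile(np.arange(11) * 0.02, np.ones(10))
        with pytest.raises(ValueError):
            ep.xcorr_profiles(a, b)


class TestTriggerAverage:
    def test_identical_trials_average_equals_trial(self, rng):
        trial = rng.standard_normal((2, 1000))
        x = np.tile(trial, (1, 5))
        rec = as_recording(x, fs=1000.0)
        avg = ep.trigger_average_lfp(rec, np.arange(5) * 1.0, (0.0, 1.0))
        np.testing.assert_allclose(avg, trial, atol=1e-12)

    def test_noise_shrinks_like_sqrt_n(self, rng):
        signal = np.sin(2 * np.pi * 5 * np.arange(1000) / 1000.0)
        resid = []
        for n in (4, 64):
            x = np.tile(signal, n) + rng.standard_normal(1000 * n)
            rec = as_recording(x, fs=1000.0)
            avg = ep.trigger_average_lfp(rec, np.arange(n) * 1.0, (0, 1.0))
            resid.append(np.std(avg[0] - signal))
        ratio = resid[0] / resid[1]
        assert ratio == pytest.approx(4.0, rel=0.25)

    def test_zero_events_rejected(self, rng):
        rec = as_recording(rng.standard_normal(1000), fs=1000.0)
        with pytest.raises(ValueError):
            ep.trigger_average_lfp(rec, np.empty(0), (0, 0.1))


class TestKL:
    def test_identical_sets_zero(self, rng):
        x = rng.standard_normal(10 ** 5)
        assert ep.kl_lfp_amplitudes(x, x.copy()).kl_value <= 1e-6

    def test_gaussian_shift_closed_form(self, rng):
        x = rng.standard_normal(10 ** 6)
        y = rng.standard_normal(10 ** 6) + 1.0
        kl = ep.kl_lfp_amplitudes(x, y, n_bins=100).kl_value
        assert kl == pytest.approx(0.5, rel=0.15)

    def test_non_negative_on_random_inputs(self, rng):
        for _ in range(20):
            x = rng.standard_normal(500) * rng.uniform(0.5, 2)
            y = rng.standard_normal(500) + rng.uniform(-1, 1)
            assert ep.kl_lfp_amplitudes(x, y, n_bins=30).kl_value >= 0

    def test_too_few_bins_rejected(self, rng):
        with pytest.raises(ValueError):
            ep.kl_lfp_amplitudes(rng.standard_normal(10),
                                 rng.standard_normal(10), n_bins=1)


class TestCSD:
    def test_linear_depth_profile_zero_interior(self):
        depths = np.arange(8)[:, None] * np.ones((1, 1000))
        csd = ep.compute_csd(depths, 100.0, 4.0, 25000.0, normalize=False)
        assert np.allclose(csd.values[1:-1], 0.0, atol=1e-9)

    def test_delta_profile_second_difference_pattern(self):
        phi = np.zeros((7, 1000))
        phi[3] = 1.0
        csd = ep.compute_csd(phi, 1000.0, 4.0, 25000.0, normalize=False)
        col = csd.values[:, 0]
        np.testing.assert_allclose(col[2:5] / abs(col[3]) * 2,
                                   [-1.0, 2.0, -1.0])

    def test_normalization_contract(self, rng):
        phi = rng.standard_normal((8, 2500))
        csd = ep.compute_csd(phi, 100.0, 10.0, 25000.0)
        assert np.abs(csd.values).max() == pytest.approx(1.0)

    def test_too_few_channels_rejected(self, rng):
        with pytest.raises(ValueError):
            ep.compute_csd(rng.standard_normal((2, 100)), 100.0, 4.0,
                           25000.0)


class TestChannelwiseCorr:
    def test_self_correlation_is_one(self, rng):
        a = rng.standard_normal((32, 60))
        rep = ep.channelwise_corr(a, a.copy(), n_shuffles=20, seed=0)
        np.testing.assert_allclose(rep.per_channel_r, 1.0, atol=1e-12)
        assert rep.pooled_r == pytest.approx(1.0)

    def test_independent_noise_small_median(self, rng):
        a = rng.standard_normal((32, 60))
        b = rng.standard_normal((32, 60))
        rep = ep.channelwise_corr(a, b, n_shuffles=20, seed=0)
        assert np.median(np.abs(rep.per_channel_r)) <= 0.15

    def test_shuffle_destroys_matching(self, rng):
        a = rng.standard_normal((32, 60))
        rep = ep.channelwise_corr(a, a.copy(), n_shuffles=100, seed=1)
        shuffled = rep.shuffled_r[np.isfinite(rep.shuffled_r)]
        assert abs(np.median(shuffled)) <= 0.05

    def test_cdfs_are_valid(self, rng):
        a = rng.standard_normal((16, 40))
        b = rng.standard_normal((16, 40))
        rep = ep.channelwise_corr(a, b, n_shuffles=10, seed=2)
        for xs, ys in (rep.matched_cdf, rep.shuffled_cdf):
            assert np.all(np.diff(xs) >= 0)
            assert np.all(np.diff(ys) >= 0)
            assert 0 < ys[0] <= 1 and ys[-1] == pytest.approx(1.0)

    def test_constant_row_skipped(self, rng):
        a = rng.standard_normal((4, 30))
        a[2] = 1.0
        rep = ep.channelwise_corr(a, rng.standard_normal((4, 30)),
                                  n_shuffles=5, seed=0)
        assert rep.skipped_channels == [2]


class TestAlongProbeCorr:
    def test_reference_channel_is_one(self, rng):
        x = rng.standard_normal((6, 500))
        r = ep.along_probe_corr(x, 0)
        assert r[0] == pytest.approx(1.0)

    @staticmethod
    def _continuous_lfp(drive, trial_length, geom):
        from somatosim.experiment import _preprocess
        rec, _ = sy.synthesize_recording(
            drive, geometry=geom, n_trials=10, trial_length=trial_length,
            seed=4)
        lfp, _ = _preprocess(rec, ep.FilterConfig())
        n = int(trial_length * lfp.sampling_rate)
        return lfp.voltages[:, n:-n:5]  # interior trials, decimated

    def test_natural_drive_decays_with_depth(self):
        from scipy import stats as spstats
        geom = sy.ProbeGeometry(16, "linear", 200.0)
        x = self._continuous_lfp(sy.make_touch_drive(0.8), 0.8, geom)
        r = ep.along_probe_corr(x, 0)
        rho, _ = spstats.spearmanr(np.arange(r.size), r)
        assert rho < 0

    def test_electrical_drive_high_similarity(self):
        # an aperiodic electrical train: a strictly 50 Hz-periodic drive
        # would be cancelled by the 50 Hz comb stage by construction
        geom = sy.ProbeGeometry(16, "linear", 200.0)
        x = self._continuous_lfp(se.make_poisson(50.0, 2.0, seed=8), 2.0,
                                 geom)
        r = ep.along_probe_corr(x, 0)
        assert np.median(r) >= 0.8

    def test_constant_reference_rejected(self, rng):
        x = rng.standard_normal((4, 100))
        x[0] = 2.0
        with pytest.raises(ValueError):
            ep.along_probe_corr(x, 0)


class TestVolleyCheck:
    def test_clear_response_detected(self, rng):
        baseline = rng.standard_normal(1000)
        response = np.r_[np.zeros(100), 5.0, -5.0, np.zeros(100)]
        assert ep.volley_check(baseline, response)

    def test_matches_direct_formula(self, rng):
        for _ in range(20):
            base = rng.standard_normal(200)
            resp = rng.standard_normal(50)
            expected = np.ptp(resp) > base.mean() + 2.5 * base.std()
            assert ep.volley_check(base, resp) == expected

    def test_zero_variance_baseline(self):
        assert ep.volley_check(np.zeros(10), np.array([0.0, 0.1]))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ep.volley_check(np.empty(0), np.ones(5))
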