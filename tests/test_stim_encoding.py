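"""Stimulation-train encoders and charge safety."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as spstats

from somatosim import stim_encoding as se


def flat_profile(value=10.0, n=200, width=0.01):
    edges = np.arange(n + 1) * width
    return se.RateProfile(edges, np.full(n, value))


class TestSmoothProfile:
    def test_constant_profile_unchanged(self):
        out = se.smooth_profile(flat_profile(), "gaussian", 0.03)
        np.testing.assert_allclose(out.rate_per_bin, 10.0, atol=1e-9)

    def test_impulse_spreads_as_discrete_gaussian(self):
        n = 101
        rates = np.zeros(n)
        rates[50] = 1.0
        prof = se.RateProfile(np.arange(n + 1) * 0.01, rates)
        out = se.smooth_profile(prof, "gaussian", 0.03)
        from scipy.ndimage import gaussian_filter1d
        expected = gaussian_filter1d(rates, 3.0, mode="reflect")
        np.testing.assert_allclose(out.rate_per_bin, expected, atol=1e-12)

    def test_mass_conserved(self):
        rng = np.random.default_rng(0)
        prof = se.RateProfile(np.arange(201) * 0.01,
                              rng.uniform(0, 50, 200))
        out = se.smooth_profile(prof, "moving_average", 0.05)
        a = prof.rate_per_bin[20:-20].sum()
        b = out.rate_per_bin[20:-20].sum()
        assert abs(a - b) / a < 0.01

    def test_width_below_bin_rejected(self):
        with pytest.raises(ValueError):
            se.smooth_profile(flat_profile(width=0.01), "gaussian", 0.005)


class TestProfileToFrequency:
    def test_affine_boundaries(self):
        rates = np.array([0.0, 5.0, 10.0])
        prof = se.RateProfile(np.arange(4) * 0.01, rates)
        freq = se.profile_to_frequency(prof, f_min=0.0, f_max=100.0)
        np.testing.assert_allclose(freq.freq_samples, [0.0, 50.0, 100.0])

    def test_constant_profile_maps_to_f_max(self):
        freq = se.profile_to_frequency(flat_profile(), 0.0, 80.0)
        np.testing.assert_allclose(freq.freq_samples, 80.0)

    def test_all_zero_rejected(self):
        prof = se.RateProfile(np.arange(4) * 0.01, np.zeros(3))
        with pytest.raises(ValueError):
            se.profile_to_frequency(prof)


class TestFrequencyToPulseTimes:
    def test_constant_profile_reduces_to_tonic(self, tonic_train):
        prof = se.FrequencyProfile(0.01, np.full(200, 50.0), 0.0, 60.0)
        train = se.frequency_to_pulse_times(prof, 2.0)
        assert len(train) == len(tonic_train) == 100
        np.testing.assert_allclose(train.pulse_onsets,
                                   tonic_train.pulse_onsets, atol=1e-9)

    def test_burst_then_silence(self):
        prof = se.FrequencyProfile(
            0.01, np.r_[np.full(100, 100.0), np.zeros(100)], 0.0, 100.0)
        train = se.frequency_to_pulse_times(prof, 2.0)
        assert len(train) == 100
        assert train.pulse_onsets.max() < 1.0

    @given(seed=st.integers(0, 50))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_count_equals_floor_of_integral(self, seed):
        rng = np.random.default_rng(seed)
        f = rng.uniform(0, 120, 150)
        prof = se.FrequencyProfile(0.01, f, 0.0, 120.0)
        train = se.frequency_to_pulse_times(prof, 1.5)
        assert len(train) == int(np.floor(np.sum(f) * 0.01 + 1e-9))


class TestComparisonEncoders:
    def test_tonic_count_and_spacing(self, tonic_train):
        assert len(tonic_train) == 100
        np.testing.assert_allclose(np.diff(tonic_train.pulse_onsets), 0.02)
        assert tonic_train.pulse_onsets[0] == 0.0
        one_hz = se.make_tonic(1.0, 2.0)
        np.testing.assert_allclose(one_hz.pulse_onsets, [0.0, 1.0])

    def test_poisson_mean_count(self):
        counts = [len(se.make_poisson(50.0, 2.0, seed=s))
                  for s in range(1000)]
        se_mc = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - 100.0) < 3 * se_mc

    def test_poisson_intervals_exponential(self):
        train = se.make_poisson(50.0, 200.0, seed=4)
        isi = np.diff(train.pulse_onsets)
        # intervals are refractory-shifted; the free part is exponential
        refractory = 2.0 * 500.0 * 1e-6 * 1.05
        stat, p = spstats.kstest(isi - refractory,
                                 "expon",
                                 args=(0, 1.0 / 50.0 - refractory))
        assert p > 0.05

    def test_poisson_seed_reproducible(self):
        a = se.make_poisson(50.0, 2.0, seed=9)
        b = se.make_poisson(50.0, 2.0, seed=9)
        np.testing.assert_array_equal(a.pulse_onsets, b.pulse_onsets)

    def test_linear_charge_follows_pressure(self):
        train = se.make_linear(np.full(2000, 0.5), 1e-3,
                               q_min_nc=10.0, q_max_nc=60.0)
        np.testing.assert_allclose(train.charge_per_pulse_nc, 35.0)
        top = se.make_linear(np.ones(2000), 1e-3, q_min_nc=10.0,
                             q_max_nc=60.0)
        np.testing.assert_allclose(top.charge_per_pulse_nc, 60.0)

    def test_linear_trapezoid_shape(self):
        t = np.arange(2000) / 1000.0
        p = np.minimum(np.minimum(t / 0.5, 1.0), (2.0 - t) / 0.5)
        p = np.clip(p, 0.0, 1.0)
        train = se.make_linear(p, 1e-3, q_min_nc=10.0, q_max_nc=60.0)
        charge = train.charge_per_pulse_nc
        mid = charge[(train.pulse_onsets > 0.5) & (train.pulse_onsets < 1.5)]
        np.testing.assert_allclose(mid, 60.0, atol=1e-6)
        rising = charge[train.pulse_onsets <= 0.5]
        assert np.all(np.diff(rising) >= -1e-9)

    def test_linear_rejects_unnormalized_pressure(self):
        with pytest.raises(ValueError):
            se.make_linear(np.array([0.0, 1.2]), 1e-3)

    def test_discrete_bursts(self):
        one = se.make_discrete([(1.0, "press")])
        assert len(one) == 25
        assert one.pulse_onsets.min() == pytest.approx(1.0)
        assert one.pulse_onsets.max() < 1.5
        two = se.make_discrete([(1.0, "press"), (3.0, "release")])
        assert len(two) == 50
        merged = se.make_discrete([(1.0, "press"), (1.2, "release")])
        assert len(merged) == 35  # [1.0, 1.7) at 50 Hz, no duplicates
        assert np.unique(merged.pulse_onsets).size == len(merged)

    def test_discrete_rejects_unsorted(self):
        with pytest.raises(ValueError):
            se.make_discrete([(2.0, "press"), (1.0, "release")])

    def test_sinusoidal_pw_quarter_points(self):
        train = se.make_sinusoidal_pw(50.0, 2.0, pw_min_us=200.0,
                                      pw_max_us=500.0, modulation_freq=1.0)
        widths = dict(zip(np.round(train.pulse_onsets, 4),
                          train.pulse_width_us))
        assert widths[0.0] == pytest.approx(350.0)
        assert widths[0.26] == pytest.approx(500.0, abs=1.0)
        assert widths[0.76] == pytest.approx(200.0, abs=1.0)
        assert train.pulse_width_us.min() >= 200.0 - 1e-9
        assert train.pulse_width_us.max() <= 500.0 + 1e-9

    def test_sinusoidal_degenerate_depth_is_tonic(self):
        train = se.make_sinusoidal_pw(50.0, 2.0, pw_min_us=300.0,
                                      pw_max_us=300.0)
        np.testing.assert_allclose(train.pulse_width_us, 300.0)


class TestChargeSafety:
    def test_reference_pulse_charge(self):
        train = se.make_tonic(50.0, 2.0, amplitude_ua=60.0,
                              pulse_width_us=500.0)
        np.testing.assert_allclose(train.charge_per_pulse_nc, 30.0)
        report = se.validate_charge(train)
        assert report.passed and report.violations == []

    def test_violation_flagged(self):
        train = se.make_tonic(50.0, 2.0, amplitude_ua=300.0,
                              pulse_width_us=500.0)
        report = se.validate_charge(train)
        assert not report.passed
        assert report.violations == list(range(100))

    def test_empty_train_passes(self):
        empty = se.StimTrain(np.empty(0), np.empty(0), np.empty(0), "TONIC")
        assert se.validate_charge(empty).passed


class TestTrainInvariants:
    @pytest.mark.parametrize("maker", [
        lambda: se.make_tonic(50.0, 2.0),
        lambda: se.make_poisson(50.0, 2.0, seed=1),
        lambda: se.make_sinusoidal_pw(50.0, 2.0),
        lambda: se.make_discrete([(0.5, "press"), (1.5, "release")]),
        lambda: se.make_linear(np.full(2000, 0.7), 1e-3),
    ])
    def test_sorted_onsets_and_exact_charge(self, maker):
        train = maker()
        assert np.all(np.diff(train.pulse_onsets) > 0)
        np.testing.assert_array_equal(
            train.charge_per_pulse_nc,
            train.amplitude_ua * train.pulse_width_us / 1000.0)

    def test_overlapping_pulses_rejected(self):
        with pytest.raises(ValueError):
            se.StimTrain(np.array([0.0, 0.0005]), 60.0, 500.0, "TONIC")


def test_biomimetic_rate_tracking():
    """The instantaneous pulse rate (1/ISI) of a biomimetic train, read on
    the PSTH grid, follows the smoothed PSTH it was designed from
    (f_min = 0)."""
    train, freq = se.design_biomimetic_train("FULL", n_units=80, seed=3,
                                             f_min=0.0, f_max=100.0)
    onsets = train.pulse_onsets
    centers = np.arange(200) * 0.01 + 0.005
    j = np.searchsorted(onsets, centers) - 1
    covered = (j >= 0) & (j < onsets.size - 1)
    inst = np.zeros(200)
    inst[covered] = 1.0 / np.diff(onsets)[j[covered]]
    r = np.corrcoef(inst, freq.freq_samples)[0, 1]
    assert r >= 0.95
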