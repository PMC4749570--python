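"""LN-model estimation: filter recovery, nonlinearity, sensitivity."""

import numpy as np
import pytest

from perigate.gating import default_temporal_filter, linear_drive
from perigate.ln import (Nonlinearity, estimate_filter, estimate_nonlinearity,
                         linear_prediction, luminance_slope, sensitivity,
                         windowed_ln)
from perigate.stimuli import (IntensityTrace, PeripheralSchedule, SpikeResponse,
                              gen_pink_noise, gen_white_noise, simulate_spikes)

DT = 1.0 / 30.0


def lnp_cell(stim, F, rate_scale=30.0, n_trials=1, seed=0):
    """Ground-truth LNP cell: threshold-linear nonlinearity on the drive."""
    g = linear_drive(stim, F)
    rate = rate_scale * np.maximum(0.0, g / np.std(g))
    return simulate_spikes(rate, n_trials, stim.dt, seed=seed), rate


class TestFilterRecovery:
    def test_white_noise_recovery(self):
        # 20 min of white noise: recovered filter matches ground truth
        F = default_temporal_filter(DT, polarity=1)
        stim = gen_white_noise(1200.0, DT, 0.3, seed=5)
        spikes, _ = lnp_cell(stim, F, seed=6)
        est = estimate_filter(stim, spikes, 0.4)
        assert np.corrcoef(est.weights, F)[0, 1] > 0.98

    def test_pink_noise_needs_whitening(self):
        F = default_temporal_filter(DT, polarity=1)
        stim = gen_pink_noise(1200.0, DT, 0.3, seed=7)
        spikes, _ = lnp_cell(stim, F, n_trials=10, seed=8)
        whitened = estimate_filter(stim, spikes, 0.4, whiten=True)
        raw = estimate_filter(stim, spikes, 0.4, whiten=False)
        c_w = np.corrcoef(whitened.weights, F)[0, 1]
        c_r = np.corrcoef(raw.weights, F)[0, 1]
        assert c_w > 0.95
        assert c_r < c_w  # raw STA is biased by stimulus autocorrelation

    def test_zero_variance_stimulus_rejected(self):
        stim = IntensityTrace(np.ones(1000), DT, 1.0, 0.0)
        spikes = SpikeResponse(np.ones((1, 1000), dtype=int), DT)
        with pytest.raises(ValueError, match="variance"):
            estimate_filter(stim, spikes)

    def test_zero_spikes_rejected(self):
        stim = gen_white_noise(30.0, DT, 0.3, seed=1)
        spikes = SpikeResponse(np.zeros((1, stim.values.size), dtype=int), DT)
        with pytest.raises(ValueError, match="zero spikes"):
            estimate_filter(stim, spikes)

    def test_unbiasedness_mean_over_runs(self):
        # average of seeded white-noise estimates converges on the truth
        F = default_temporal_filter(DT, polarity=1)
        ests = []
        for seed in range(12):
            stim = gen_white_noise(120.0, DT, 0.3, seed=100 + seed)
            spikes, _ = lnp_cell(stim, F, seed=200 + seed)
            ests.append(estimate_filter(stim, spikes).weights)
        mean_est = np.mean(ests, axis=0)
        assert np.corrcoef(mean_est, F)[0, 1] > 0.995


class TestLinearPrediction:
    def test_single_tap_identity(self):
        stim = gen_white_noise(10.0, DT, 0.2, seed=3)
        g = linear_prediction(stim, np.array([1.0]), normalize=False)
        np.testing.assert_allclose(g, stim.values - stim.values.mean())

    def test_variance_matched(self):
        stim = gen_pink_noise(100.0, DT, 0.2, seed=4)
        g = linear_prediction(stim, default_temporal_filter(DT))
        assert np.isclose(np.var(g), np.var(stim.values), rtol=1e-9)

    def test_against_direct_sum_oracle(self):
        F = np.array([0.5, -0.2, 0.1])
        vals = np.array([1.0, 2.0, 0.5, -1.0, 3.0])
        stim = IntensityTrace(vals, DT, vals.mean(), 0.0)
        s = vals - vals.mean()
        expected = np.array([sum(F[k] * s[t - k] for k in range(3)
                                 if t - k >= 0) for t in range(5)])
        g = linear_prediction(stim, F, normalize=False)
        np.testing.assert_allclose(g, expected, atol=1e-9)


class TestNonlinearity:
    def test_threshold_linear_recovery(self):
        F = default_temporal_filter(DT, polarity=1)
        stim = gen_white_noise(600.0, DT, 0.3, seed=9)
        spikes, rate = lnp_cell(stim, F, n_trials=20, seed=10)
        g = linear_prediction(stim, F) / np.std(linear_prediction(stim, F))
        nl = estimate_nonlinearity(g, spikes, n_bins=10)
        expected = 30.0 * np.maximum(0.0, nl.bin_centers)
        # Poisson SE of each bin mean rate
        se = np.sqrt(np.maximum(expected, 1.0) /
                     (nl.occupancy * 20 * DT))
        assert np.all(np.abs(nl.mean_rate - expected) < 4 * se)

    def test_rate_independent_of_g_is_flat(self, rng):
        g = rng.standard_normal(20000)
        rate = np.full(20000, 7.0)
        nl = estimate_nonlinearity(g, rate, n_bins=8)
        np.testing.assert_allclose(nl.mean_rate, 7.0, atol=1e-9)
        assert abs(sensitivity(nl)) < 1e-9

    def test_occupancy_conservation(self, rng):
        g = rng.standard_normal(5000)
        nl = estimate_nonlinearity(g, np.abs(g) * 10, n_bins=12)
        assert nl.occupancy.sum() == 5000

    def test_rebin_consistency(self, rng):
        # 8 vs 16 bins give consistent sensitivity on a smooth ground truth
        g = rng.standard_normal(60000)
        rate = 20.0 / (1.0 + np.exp(-2 * g))
        s8 = sensitivity(estimate_nonlinearity(g, rate, n_bins=8))
        s16 = sensitivity(estimate_nonlinearity(g, rate, n_bins=16))
        assert abs(s8 - s16) / s16 < 0.15


class TestWindowedLN:
    def test_full_window_equals_unwindowed(self, pink_gating_run):
        r = pink_gating_run
        full = windowed_ln(r["stim"], r["spikes"], r["schedule"],
                           (0.0, 0.5), whiten=True, smooth=0.05)
        none = windowed_ln(r["stim"], r["spikes"], None, None,
                           whiten=True, smooth=0.05)
        np.testing.assert_allclose(full.filter.weights, none.filter.weights,
                                   atol=1e-9)

    def test_empty_window_rejected(self, pink_gating_run):
        r = pink_gating_run
        with pytest.raises(ValueError):
            windowed_ln(r["stim"], r["spikes"], r["schedule"], (0.6, 0.7))

    def test_low_data_warning_in_metadata(self, pink_gating_run):
        r = pink_gating_run
        whole = windowed_ln(r["stim"], r["spikes"], None, None,
                            whiten=True, smooth=0.05)
        # the deep-suppression window holds very few spikes
        model = windowed_ln(r["stim"], r["spikes"], r["schedule"],
                            (0.25, 0.275), filt=whole.filter)
        n_window = int(np.where(
            ((r["schedule"].time_since_shift(r["spikes"].times)[0] >= 0.25)
             & (r["schedule"].time_since_shift(r["spikes"].times)[0] < 0.275)
             )[None, :], r["spikes"].counts, 0).sum())
        if n_window < 50:
            assert "low_data_warning" in model.meta
        else:
            assert "low_data_warning" not in model.meta


class TestSensitivity:
    def test_exact_line(self):
        nl = Nonlinearity(np.array([0.0, 1.0, 2.0, 3.0]),
                          np.array([1.0, 4.0, 7.0, 10.0]),
                          np.array([5, 5, 5, 5]))
        assert np.isclose(sensitivity(nl), 3.0, atol=1e-12)

    def test_linearity_in_rates(self, rng):
        x = np.sort(rng.standard_normal(6))
        y = rng.random(6) * 10
        occ = rng.integers(1, 100, 6)
        s1 = sensitivity(Nonlinearity(x, y, occ))
        s2 = sensitivity(Nonlinearity(x, 2 * y, occ))
        assert np.isclose(s2, 2 * s1, atol=1e-12)

    def test_weighted_finite_difference_oracle(self, rng):
        x = np.sort(rng.standard_normal(6))
        y = rng.random(6) * 10
        occ = rng.integers(1, 100, 6).astype(float)
        slopes = np.empty(6)
        slopes[0] = (y[1] - y[0]) / (x[1] - x[0])
        slopes[-1] = (y[-1] - y[-2]) / (x[-1] - x[-2])
        for i in range(1, 5):
            slopes[i] = (y[i + 1] - y[i - 1]) / (x[i + 1] - x[i - 1])
        expected = np.sum(occ * slopes) / occ.sum()
        got = sensitivity(Nonlinearity(x, y, occ.astype(int)))
        assert np.isclose(got, expected, atol=1e-12)

    def test_single_bin_undefined(self):
        nl = Nonlinearity(np.array([0.0]), np.array([1.0]), np.array([10]))
        with pytest.raises(ValueError):
            sensitivity(nl)


class TestLuminanceSlope:
    def test_exact_log_linear(self):
        lum = np.array([0.5, 1.0, 2.0, 4.0])
        rates = 3.0 * np.log(lum) + 1.0
        assert np.isclose(luminance_slope(lum, rates), 3.0, atol=1e-9)

    def test_identical_rates_zero_slope(self):
        lum = np.array([0.5, 1.0, 2.0, 4.0])
        assert np.isclose(luminance_slope(lum, np.full(4, 5.0)), 0.0,
                          atol=1e-9)

    def test_nonpositive_luminance_rejected(self):
        with pytest.raises(ValueError):
            luminance_slope(np.array([0.0, 1.0]), np.array([1.0, 2.0]))
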