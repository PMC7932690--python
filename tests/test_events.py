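"""SWR / locomotion / multi-band transient detection and triggered averages."""

import numpy as np
import pytest

import choxamp as cx
from choxamp.synth import (gen_lfp_with_ripples, gen_o2_events,
                           gen_slow_signals, gen_speed_trace)


class TestSWR:
    def test_recall_and_timing_on_synthetic_bursts(self, rng):
        times = np.sort(rng.uniform(5, 115, 25))
        times = times[np.concatenate([[True], np.diff(times) > 1.0])]
        lfp, _ = gen_lfp_with_ripples(times, 120.0, fs=1000, snr=5, seed=7)
        ev = cx.detect_swr(lfp, 1000.0)
        errs = []
        for tt in times:
            d = np.abs(ev.times - tt).min()
            if d < 0.05:
                errs.append(d)
        assert len(errs) / len(times) >= 0.9
        assert np.median(errs) < 0.010

    def test_noise_only_false_positive_rate(self):
        lfp, _ = gen_lfp_with_ripples([], 120.0, fs=1000, seed=8)
        ev = cx.detect_swr(lfp, 1000.0)
        assert len(ev) / 120.0 < 0.05

    def test_long_burst_rejected_by_duration(self):
        fs = 1000.0
        lfp, truth = gen_lfp_with_ripples([], 60.0, fs=fs, seed=9)
        t = np.arange(lfp.size) / fs
        # 350 ms tapered-flat 150 Hz burst: supra-threshold > 200 ms
        from scipy.signal.windows import tukey
        nb = 350
        i0 = 30_000 - nb // 2
        env = np.zeros_like(lfp)
        env[i0:i0 + nb] = 6 * truth["band_sd"] * tukey(nb, 0.2)
        lfp = lfp + env * np.sin(2 * np.pi * 150.0 * t)
        ev = cx.detect_swr(lfp, fs)
        assert not np.any(np.abs(ev.times - 30.0) < 0.3)
        assert np.all(ev.durations < 0.2)
        assert np.all(ev.extras["cycles"] >= 5)

    def test_scale_invariance_of_percentile_threshold(self):
        lfp, _ = gen_lfp_with_ripples(np.arange(5, 60, 5.0), 60.0, fs=1000,
                                      snr=6, seed=10)
        e1 = cx.detect_swr(lfp, 1000.0)
        e2 = cx.detect_swr(3.7 * lfp, 1000.0)
        assert np.array_equal(e1.times, e2.times)

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError):
            cx.detect_swr(np.zeros(1000), 500.0)


class TestLocomotion:
    def test_constant_speed_gives_empty_set(self):
        ev = cx.detect_locomotion_bouts(np.full(600, 3.0), 1.0, threshold=0.5)
        assert len(ev) == 0

    def test_bouts_recovered_within_one_second(self):
        bouts = [60.0, 180.0, 300.0, 420.0]
        speed, _ = gen_speed_trace(bouts, 500.0, seed=11)
        ev = cx.detect_locomotion_bouts(speed, 1.0, threshold=2.0)
        assert len(ev) == len(bouts)
        for b in bouts:
            assert np.abs(ev.times - b).min() <= 1.0

    def test_threshold_above_maximum_gives_empty_set(self):
        speed, _ = gen_speed_trace([100.0], 300.0, seed=12)
        ev = cx.detect_locomotion_bouts(speed, 1.0, threshold=1e9)
        assert len(ev) == 0


class TestMultiband:
    def test_scaled_copy_gives_constant_slope_zero_lag(self, rng):
        evs = gen_o2_events(rng, 2000.0, t_start=40.0, n_events=40)
        _, o2, coa, _ = gen_slow_signals(2000.0, 10.0, evs,
                                         ("linear", {"gain": 0.5}), seed=13)
        for band in cx.detect_transients_multiband(o2, coa, 10.0):
            assert band.slope == pytest.approx(0.5, rel=0.02)
            assert abs(np.median(band.lags)) <= 0.1

    def test_isolated_o2_peak_without_coa_yields_no_pair(self):
        t = np.arange(6000) / 10.0
        o2 = np.exp(-0.5 * ((t - 300.0) / 4.0) ** 2)
        coa = np.zeros_like(o2)
        for band in cx.detect_transients_multiband(o2, coa, 10.0):
            assert len(band) == 0
            assert np.isnan(band.slope)

    def test_pairing_invariant_under_common_time_shift(self, rng):
        evs = gen_o2_events(rng, 1500.0, t_start=40.0, n_events=25)
        _, o2, coa, _ = gen_slow_signals(1500.0, 10.0, evs,
                                         ("linear", {"gain": 0.7}), seed=14)
        shift = 200  # samples
        b0 = cx.detect_transients_multiband(o2[:-shift], coa[:-shift], 10.0)
        b1 = cx.detect_transients_multiband(o2[shift:], coa[shift:], 10.0)
        for x, y in zip(b0, b1):
            if len(x) and len(y):
                assert np.median(x.lags) == pytest.approx(np.median(y.lags),
                                                          abs=0.21)

    def test_band_rise_times_decrease_with_corner_freq(self, rng):
        evs = gen_o2_events(rng, 2500.0, t_start=40.0, n_events=50)
        _, o2, coa, _ = gen_slow_signals(2500.0, 10.0, evs,
                                         ("linear", {"gain": 0.5}), seed=15)
        bands = cx.detect_transients_multiband(o2, coa, 10.0)
        rises = [b.rise_time for b in bands]
        assert np.all(np.diff(rises) < 0)


class TestRippleCorrelation:
    def make_inputs(self, rng, lag=3.0):
        fs = 10.0
        n = int(1200 * fs)
        power = np.abs(rng.standard_normal(n)) + 0.1
        swr_times = np.sort(rng.uniform(30, 1170, 60))
        sm = np.convolve(power, np.ones(20) / 20, mode="same")
        sig = np.roll(sm, int(lag * fs)) + 0.01 * rng.standard_normal(n)
        return sig, power, swr_times, fs

    def test_constructed_lag_is_recovered(self, rng):
        sig, power, swr, fs = self.make_inputs(rng, lag=3.0)
        cm = cx.ripple_power_correlation(sig, fs, power, fs, swr,
                                         window_sizes=[2.0],
                                         lags=np.arange(0.0, 8.0, 0.5))
        best = cm.lags[np.argmax(cm.corr[0])]
        assert abs(best - 3.0) <= 1.0

    def test_rank_invariance_under_amplitude_scaling(self, rng):
        sig, power, swr, fs = self.make_inputs(rng)
        lags = np.arange(0.0, 6.0, 1.0)
        c1 = cx.ripple_power_correlation(sig, fs, power, fs, swr, [2.0], lags)
        c2 = cx.ripple_power_correlation(2 * sig, fs, power, fs, swr, [2.0],
                                         lags)
        assert np.allclose(c1.corr, c2.corr)

    def test_independent_signal_mostly_non_significant(self, rng):
        sig, power, swr, fs = self.make_inputs(rng)
        indep = rng.standard_normal(sig.size)
        cm = cx.ripple_power_correlation(indep, fs, power, fs, swr,
                                         [1.0, 2.0, 4.0],
                                         np.arange(-2.0, 6.0, 1.0))
        assert cm.significant.mean() <= 0.2

    def test_too_few_events_rejected(self, rng):
        sig, power, _, fs = self.make_inputs(rng)
        with pytest.raises(ValueError):
            cx.ripple_power_correlation(sig, fs, power, fs, [1.0, 2.0],
                                        [2.0], [0.0])


class TestTriggeredAverage:
    def test_identical_pulses_reproduced_with_zero_ci_width(self):
        fs = 10.0
        x = np.zeros(int(600 * fs))
        t = np.arange(x.size) / fs
        events = np.array([100.0, 200.0, 300.0, 400.0])
        for ev in events:
            x += 5.0 * np.exp(-0.5 * ((t - ev - 2.0) / 1.0) ** 2)
        res = cx.event_triggered_average(x, fs, events, window=(-5.0, 10.0),
                                         rng=0)
        pulse = 5.0 * np.exp(-0.5 * ((res.t - 2.0) / 1.0) ** 2)
        assert np.allclose(res.mean, pulse, atol=1e-6)
        assert np.allclose(res.ci_high - res.ci_low, 0.0, atol=1e-9)
        # derivative-rule onset of a Gaussian sits at the inflection point
        # (peak - 1 sigma), so amplitude = peak * (1 - exp(-1/2))
        assert res.amplitude == pytest.approx(5.0 * (1 - np.exp(-0.5)),
                                              rel=0.02)
        assert res.peak_time == pytest.approx(2.0, abs=0.2)

    def test_ci_width_shrinks_with_event_count(self, rng):
        fs = 10.0
        dur = 5000.0
        x = rng.standard_normal(int(dur * fs))
        small = rng.uniform(20, dur - 20, 25)
        large = rng.uniform(20, dur - 20, 100)
        w_small = cx.event_triggered_average(x, fs, small, rng=1)
        w_large = cx.event_triggered_average(x, fs, large, rng=2)
        ratio = (np.mean(w_small.ci_high - w_small.ci_low)
                 / np.mean(w_large.ci_high - w_large.ci_low))
        assert ratio == pytest.approx(2.0, rel=0.35)

    def test_out_of_bounds_events_dropped_and_empty_result(self):
        x = np.zeros(1000)
        res = cx.event_triggered_average(x, 10.0, [5000.0], window=(-1, 1))
        assert res.n_used == 0 and res.n_dropped == 1
        partial = cx.event_triggered_average(x, 10.0, [50.0, 5000.0],
                                             window=(-1, 1))
        assert partial.n_used == 1 and partial.n_dropped == 1


def test_exclusion_mask_windows():
    m = cx.exclusion_mask(1000, 10.0, swr_times=[50.0],
                          speed_peak_times=[20.0])
    assert m[int(46 * 10)] and m[int(50.5 * 10)] and not m[int(52 * 10)]
    assert m[int(7 * 10)] and m[int(23 * 10)] and not m[int(25 * 10)]
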