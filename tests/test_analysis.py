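"""Phase analytics, spike-triggered averages, corrected correlograms, f-I."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dendrhythm import analysis as ana
from dendrhythm.core import RhythmSpec


class TestSTA:
    def test_constant_presence_zero_change(self):
        binaries = np.ones((3, 500), dtype=bool)
        res = ana.sta_percent_change(binaries, np.array([200.0, 400.0]))
        np.testing.assert_allclose(res.pct, 0.0, atol=1e-12)

    def test_events_only_at_ap_times(self):
        n = 2000
        aps = np.array([100.0, 500.0, 900.0])
        b = np.zeros((1, n), dtype=bool)
        idx = (aps / 2.0).astype(int)
        b[0, idx] = True
        res = ana.sta_percent_change(b, aps, max_lag=20.0)
        mean = b.mean()
        lag0 = res.pct[0, res.lags.size // 2]
        assert lag0 == pytest.approx(100.0 * (1.0 / mean - 1.0), rel=1e-9)

    def test_independent_events_flat(self):
        rng = np.random.default_rng(0)
        b = rng.random((5, 20000)) < 0.2
        aps = np.sort(rng.uniform(100, 39000, 200))
        res = ana.sta_percent_change(b, aps, max_lag=30.0)
        # binomial sd per (comp, lag): sqrt(p(1-p)/n)/p
        sd_pct = 100 * np.sqrt(0.8 / (0.2 * 200))
        assert np.abs(res.pct).max() < 4 * sd_pct

    def test_zero_mean_compartment_excluded(self):
        b = np.zeros((2, 100), dtype=bool)
        b[0, ::7] = True
        with pytest.warns(UserWarning):
            res = ana.sta_percent_change(b, np.array([100.0]))
        assert res.pct.shape[0] == 1


class TestPhase:
    def test_convention_extrema(self):
        spec = RhythmSpec(10.0, 0.3, offset=5.0)
        # inhibitory rate r(t) = A sin(2 pi f t) + off: max at t = T/4
        T = spec.period
        assert ana.phase_of(T / 4.0, spec) == pytest.approx(0.0, abs=1e-9)
        assert abs(ana.phase_of(3 * T / 4.0, spec)) == pytest.approx(
            np.pi, abs=1e-9)

    def test_periodicity(self):
        spec = RhythmSpec(7.0, 0.2)
        t = np.array([3.0, 11.0, 40.0])
        np.testing.assert_allclose(ana.phase_of(t, spec),
                                   ana.phase_of(t + spec.period, spec),
                                   atol=1e-9)

    def test_peak_trough_split_half(self):
        spec = RhythmSpec(5.0, 0.4)
        t = np.linspace(0.0, 4000.0, 100000)
        mask = ana.peak_trough_masks(spec, t)
        assert mask.mean() == pytest.approx(0.5, abs=0.01)
        assert ana.peak_trough_masks(spec, np.array([spec.period / 4]))[0]
        assert not ana.peak_trough_masks(
            spec, np.array([3 * spec.period / 4]))[0]


class TestPhaseHistogram:
    def test_uniform_events_flat(self):
        spec = RhythmSpec(10.0, 0.3)
        b = np.ones(5000, dtype=bool)
        ph = ana.phase_histogram(b, spec)
        np.testing.assert_allclose(ph.pct, 0.0, atol=1e-9)
        assert ph.edges.size == 9  # 8 bins

    def test_concentrated_events(self):
        # all events in one bin: +700% there, -100% elsewhere.  A 62.5 Hz
        # rhythm puts exactly one 2 ms sample in each of the 8 phase bins
        # per cycle, so the bin occupancies are equal and the arithmetic
        # is exact.
        spec = RhythmSpec(62.5, 0.3)
        n = 40000
        t = 2.0 * (np.arange(n) + 0.5)
        phase = ana.phase_of(t, spec)
        edges = np.linspace(-np.pi, np.pi, 9)
        which = np.clip(np.searchsorted(edges, phase, "left") - 1, 0, 7)
        b = which == 3
        ph = ana.phase_histogram(b, spec)
        assert ph.pct[3] == pytest.approx(700.0, rel=1e-9)
        others = np.delete(ph.pct, 3)
        np.testing.assert_allclose(others, -100.0, atol=1e-9)

    def test_occupancy_weighted_mean_recovers_global_mean(self):
        rng = np.random.default_rng(1)
        spec = RhythmSpec(13.0, 0.3)
        b = rng.random(30000) < 0.1
        ph = ana.phase_histogram(b, spec)
        weighted = np.nansum(ph.raw * ph.occupancy) / ph.occupancy.sum()
        assert weighted == pytest.approx(b.mean(), rel=1e-9)


class TestPPC:
    def test_identical_phases(self):
        assert ana.ppc(np.zeros(50) + 1.2) == pytest.approx(1.0)

    def test_antipodal_pair(self):
        assert ana.ppc(np.array([0.0, np.pi])) == pytest.approx(-1.0)

    def test_uniform_phases_near_zero(self):
        rng = np.random.default_rng(7)
        vals = [ana.ppc(rng.uniform(-np.pi, np.pi, 1000)) for _ in range(20)]
        # unbiased: mean 0, sd ~ sqrt(2)/n
        assert abs(np.mean(vals)) < 0.01

    def test_single_phase_rejected(self):
        with pytest.raises(ValueError):
            ana.ppc(np.array([0.1]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(2, 200), st.integers(0, 10 ** 6))
    def test_equals_unbiased_resultant_form(self, n, seed):
        # PPC == (n*R^2 - 1)/(n - 1) with R the resultant length
        rng = np.random.default_rng(seed)
        ph = rng.uniform(-np.pi, np.pi, n)
        r2 = np.abs(np.mean(np.exp(1j * ph))) ** 2
        expect = (n * r2 - 1.0) / (n - 1.0)
        assert ana.ppc(ph) == pytest.approx(expect, abs=1e-12)


class TestCorrectedCC:
    def test_delta_coupling_peak_at_lag(self):
        rng = np.random.default_rng(3)
        pre = np.sort(rng.uniform(0, 50000, 400))
        cc = ana.phase_stratified_cc(pre, pre + 3.0, 50000.0, None)
        assert cc.lags[int(np.argmax(cc.cc))] == pytest.approx(3.0)
        assert cc.peak_area > 0

    def test_comodulated_independent_trains_flat(self):
        # two independent trains sharing a 16 Hz rate modulation: after
        # correction the CC must be flat against jittered surrogates
        from dendrhythm.core import RhythmSpec
        from dendrhythm import inputs as inp
        spec = RhythmSpec(16.0, 0.4, offset=20.0)
        dur = 120000.0
        rate = inp.sine_rate(spec, dur, 1.0)
        a = inp.sample_poisson(rate, seed=1).times
        b = inp.sample_poisson(rate, seed=2).times
        cc = ana.phase_stratified_cc(a, b, dur, 16.0)
        # jitter surrogates destroy any fine-time structure
        rng = np.random.default_rng(0)
        null = []
        for _ in range(20):
            aj = np.sort(a + rng.uniform(-8, 8, a.size))
            null.append(np.abs(ana.phase_stratified_cc(
                aj, b, dur, 16.0).cc).max())
        assert np.abs(cc.cc).max() < np.mean(null) + 3 * np.std(null)

    def test_correction_removes_rhythm_power(self):
        from dendrhythm.core import RhythmSpec
        from dendrhythm import inputs as inp
        spec = RhythmSpec(16.0, 0.4, offset=20.0)
        dur = 60000.0
        rate = inp.sine_rate(spec, dur, 1.0)
        a = inp.sample_poisson(rate, seed=3).times
        b = inp.sample_poisson(rate, seed=4).times
        raw = ana.phase_stratified_cc(a, b, dur, None, max_lag=100.0)
        cor = ana.phase_stratified_cc(a, b, dur, 16.0, max_lag=100.0)

        def power_at(cc, f):
            sp = np.abs(np.fft.rfft(cc.cc)) ** 2
            fr = np.fft.rfftfreq(cc.cc.size, d=1e-3)
            return sp[np.argmin(np.abs(fr - f))]

        assert power_at(cor, 16.0) < 0.05 * power_at(raw, 16.0)

    def test_triangle_peak_area_matches_closed_form(self):
        lags = np.arange(-50.0, 51.0)
        cc = np.maximum(0.0, 1.0 - np.abs(lags - 3.0) / 10.0)
        area = ana._peak_area(lags, cc, 1.0)
        assert area == pytest.approx(10.0, rel=0.02)  # base 20, height 1

    def test_empty_stratum_warns(self):
        spec = RhythmSpec(10.0, 0.3)
        with pytest.warns(UserWarning):
            res = ana.phase_stratified_cc(
                np.array([]), np.array([5.0]), 100.0, 10.0, spec, "peak")
        assert res.peak_area == 0.0


class TestFI:
    def test_all_subthreshold(self):
        fi = ana.fi_from_counts(np.array([-1.0, 0.0]), np.array([0, 0]),
                                2000.0)
        assert np.isnan(fi.threshold) and np.isnan(fi.slope)
        assert np.all(fi.rates == 0)

    def test_printed_grid_has_18_steps(self):
        amps = np.arange(-1.0, 2.401, 0.2)
        assert amps.size == 18

    def test_threshold_and_slope_arithmetic(self):
        amps = np.arange(0.0, 1.01, 0.25)
        counts = np.array([0, 0, 10, 20, 30])
        fi = ana.fi_from_counts(amps, counts, 1000.0)
        assert fi.threshold == pytest.approx(0.5)
        assert fi.slope == pytest.approx(40.0)  # 10 Hz per 0.25 nA

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            ana.fi_from_counts(np.array([1.0, 0.0]), np.array([0, 0]), 1000.0)


class TestAPThreshold:
    def test_ramp_value_at_one_ms_before_peak(self):
        dt = 0.1
        v = 0.5 * dt * np.arange(3000)  # ramp 0.5 mV/ms
        out = ana.ap_threshold(v, dt, np.array([200.0]))
        assert out[0] == pytest.approx(v[int(199.0 / dt)])

    def test_translation_property(self):
        rng = np.random.default_rng(2)
        v = rng.normal(-60, 3, 5000)
        peaks = np.array([100.0, 250.0, 400.0])
        a = ana.ap_threshold(v, 0.1, peaks)
        b = ana.ap_threshold(v + 7.5, 0.1, peaks)
        np.testing.assert_allclose(b - a, 7.5, atol=1e-12)

    def test_early_peak_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            out = ana.ap_threshold(np.zeros(100), 0.1,
                                   np.array([0.5, 5.0]))
        assert out.size == 1


class TestFluctuationBias:
    def test_constant_trace_zero(self):
        spec = RhythmSpec(64.0, 0.4)
        out = ana.fluctuation_bias(np.full(20000, -60.0), 0.1, spec)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_linear_ramp_uniform_bias(self):
        spec = RhythmSpec(64.0, 0.4)
        v = 0.3 * 0.1 * np.arange(50000)
        out = ana.fluctuation_bias(v, 0.1, spec)
        np.testing.assert_allclose(out, 0.3, atol=1e-9)

    def test_sinusoid_bias_tracks_discrete_derivative(self):
        spec = RhythmSpec(16.0, 0.3)
        dt = 0.1
        t = dt * (1 + np.arange(400000))
        ph = ana.phase_of(t, spec)
        v = np.sin(2 * np.pi * 16.0 * t / 1000.0)
        out = ana.fluctuation_bias(v, dt, spec)
        centers = -np.pi + np.pi / 4 * (0.5 + np.arange(8))
        # v = sin(theta + pi/2) = cos(theta): dV/dt ~ -sin(theta)
        expect = np.diff(np.sin(2 * np.pi * 16 / 1000 *
                                np.arange(2)))[0]  # scale check only
        assert np.corrcoef(out, -np.sin(centers))[0, 1] > 0.99


class TestSTAvsPhaseAgreement:
    def test_phase_locked_events_localized_by_both(self):
        # events deterministically at the rhythm trough: the phase
        # histogram peaks at +-pi and the STA around (phase-locked) APs is
        # strongly modulated
        spec = RhythmSpec(10.0, 0.3)
        dur = 60000.0
        trough_times = spec.period * (0.75 + np.arange(int(dur / spec.period) - 1))
        b_idx = (trough_times / 2.0).astype(int)
        b = np.zeros(int(dur / 2.0), dtype=bool)
        b[b_idx] = True
        ph = ana.phase_histogram(b, spec)
        assert int(np.argmax(ph.pct)) in (0, 7)
        sta = ana.sta_percent_change(b[None, :], trough_times, max_lag=40.0)
        # the STA peaks at zero lag (within one bin of trigger rounding)
        assert abs(sta.lags[int(np.argmax(sta.pct[0]))]) <= 2.0
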