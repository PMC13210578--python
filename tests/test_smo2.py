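"""SmO2 kinetic metrics: slopes, 63%-increment tau, Rep 10 s, bundle analyzers."""

import math

import numpy as np
import pytest

from muscleox import (CuffSimConfig, ExclusionError, ProtocolEvents,
                      SampledTrace, SseSimConfig, UndefinedMetricError,
                      analyze_cuff, analyze_sse, gen_cuff_trace, gen_sse_trace,
                      occlusion_slope, relative_rate, reox_increment_tau,
                      rep10s)

LN037 = -math.log(0.37)  # tau of the 63% threshold on a true exponential


def make_trace(values, rate=10.0, t0=0.0):
    return SampledTrace(np.asarray(values, dtype=float), rate=rate, t0=t0)


def exp_recovery(v0=40.0, increment=30.0, tau=10.0, pre_s=30.0, total_s=150.0,
                 rate=10.0):
    """Plateau at v0, then mono-exponential rise of `increment` from t=pre_s."""
    t = np.arange(0.0, total_s, 1.0 / rate)
    v = np.where(t < pre_s, v0,
                 v0 + increment * (1.0 - np.exp(-(t - pre_s) / tau)))
    return make_trace(v, rate=rate), pre_s


class TestOcclusionSlope:
    def test_exact_line_recovers_slope(self):
        t = np.arange(0.0, 240.0, 0.1)
        trace = make_trace(65.0 - 0.06 * t)
        assert occlusion_slope(trace, 30.0, 210.0) == pytest.approx(-0.06, abs=1e-12)

    def test_constant_trace_zero_slope(self):
        trace = make_trace([65.0] * 2400)
        assert occlusion_slope(trace, 30.0, 210.0) == pytest.approx(0.0, abs=1e-12)

    def test_generator_round_trip(self):
        trace, ev, _ = gen_cuff_trace(CuffSimConfig(desat_slope=-0.07, noise_sd=0.0))
        slope = occlusion_slope(trace, ev.cuff_inflate_t, ev.cuff_release_t)
        assert slope == pytest.approx(-0.07, abs=1e-9)

    def test_time_origin_invariance(self):
        t = np.arange(0.0, 240.0, 0.1)
        v = 65.0 - 0.05 * t
        a = occlusion_slope(make_trace(v, t0=0.0), 30.0, 210.0)
        b = occlusion_slope(make_trace(v, t0=500.0), 530.0, 710.0)
        assert a == pytest.approx(b, abs=1e-12)

    def test_insufficient_data_rejected(self):
        vals = np.full(2400, np.nan)
        vals[:100] = 60.0
        from muscleox import QualityError
        with pytest.raises(QualityError):
            occlusion_slope(make_trace(vals), 30.0, 210.0)


class TestReoxIncrementTau:
    def test_noiseless_exponential_exact_grid_values(self):
        trace, t_start = exp_recovery(v0=40.0, increment=30.0, tau=10.0)
        inc, tau = reox_increment_tau(trace, t_start, target="fixed_level",
                                      level=70.0)
        assert inc == pytest.approx(30.0, abs=1e-9)
        # first grid point with 1 - e^(-t/10) >= 0.63 is exactly t = 10.0
        assert tau == pytest.approx(10.0, abs=1e-12)

    def test_peak_in_window_with_plateau(self):
        trace, t_start = exp_recovery(v0=40.0, increment=30.0, tau=5.0,
                                      total_s=200.0)
        inc, tau = reox_increment_tau(trace, t_start, target="peak_in_window",
                                      window_s=100.0)
        assert inc == pytest.approx(30.0, rel=1e-6)
        assert 5.0 * LN037 <= tau <= 5.0 * LN037 + 0.1 + 1e-9

    def test_flat_recovery_undefined(self):
        trace = make_trace([50.0] * 600)
        with pytest.raises(UndefinedMetricError):
            reox_increment_tau(trace, 10.0, target="fixed_level", level=50.0)

    def test_step_recovery_tau_is_one_sample(self):
        v = np.where(np.arange(600) < 300, 40.0, 70.0)
        trace = make_trace(v)
        inc, tau = reox_increment_tau(trace, 29.9, target="fixed_level",
                                      level=70.0)
        assert tau == pytest.approx(0.1)

    def test_never_crossed_undefined(self):
        # recovers only 40% of the claimed increment
        trace, t_start = exp_recovery(v0=40.0, increment=12.0, tau=5.0)
        with pytest.raises(UndefinedMetricError):
            reox_increment_tau(trace, t_start, target="fixed_level", level=70.0)

    @pytest.mark.parametrize("tau_true", [5.0, 8.0, 10.0, 12.0, 16.0, 20.0])
    def test_grid_bracket_property(self, tau_true):
        """tau-hat lies in [tau*ln(1/0.37), tau*ln(1/0.37) + dt] noiselessly."""
        trace, t_start = exp_recovery(tau=tau_true, total_s=300.0)
        _, tau = reox_increment_tau(trace, t_start, target="fixed_level",
                                    level=70.0)
        assert tau_true * LN037 - 1e-9 <= tau <= tau_true * LN037 + 0.1 + 1e-9


class TestRelativeRate:
    def test_arithmetic(self):
        assert relative_rate(30.0, 10.0) == pytest.approx(3.0)
        assert relative_rate(0.0, 10.0) == 0.0
        # per-recording ratio, not a group mean of ratios
        assert relative_rate(5.87, 14.5) == pytest.approx(0.404827, abs=1e-6)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            relative_rate(5.0, 0.0)


class TestRep10s:
    def test_exponential_against_direct_sample_oracle(self):
        trace, t_start = exp_recovery(v0=40.0, increment=30.0, tau=10.0)
        got = rep10s(trace, t_start)
        i0a, i0b = trace.window_indices(t_start - 0.5, t_start)
        i1a, i1b = trace.window_indices(t_start + 9.5, t_start + 10.0)
        oracle = (trace.values[i1a:i1b].mean() - trace.values[i0a:i0b].mean()) / 10.0
        assert got == pytest.approx(oracle, abs=1e-12)
        # closed form sanity: near (v(10) - v(0))/10 = 1.896 %/s
        assert got == pytest.approx(1.896, abs=0.05)

    def test_constant_trace_zero(self):
        assert rep10s(make_trace([55.0] * 600), 20.0) == pytest.approx(0.0)

    def test_linear_rise_slope_invariant_under_endpoint_averaging(self):
        t = np.arange(0.0, 60.0, 0.1)
        trace = make_trace(10.0 + 1.0 * t)
        assert rep10s(trace, 20.0) == pytest.approx(1.0, abs=1e-9)

    def test_offset_invariance(self):
        trace, t_start = exp_recovery()
        shifted = trace.with_values(trace.values + 17.3)
        assert rep10s(shifted, t_start) == pytest.approx(
            rep10s(trace, t_start), abs=1e-9)

    def test_slope_mode_matches_polyfit(self):
        trace, t_start = exp_recovery()
        got = rep10s(trace, t_start, mode="slope")
        i0, i1 = trace.window_indices(t_start, t_start + 10.0)
        oracle = np.polyfit(trace.times[i0:i1], trace.values[i0:i1], 1)[0]
        assert got == pytest.approx(oracle, abs=1e-12)


class TestAnalyzeCuff:
    def test_noiseless_round_trip(self):
        cfg = CuffSimConfig(tau_true=8.0, overshoot_pct=5.0, noise_sd=0.0)
        trace, ev, truth = gen_cuff_trace(cfg)
        m = analyze_cuff(trace, ev)
        assert m.baseline_smo2 == pytest.approx(65.0, abs=1e-6)
        assert m.occlusion_slope == pytest.approx(-0.06, abs=1e-9)
        assert m.tau_peak == pytest.approx(8.0 * -math.log(0.37), abs=0.11)
        assert m.i_peak == pytest.approx(truth["i_true"], rel=0.02)
        assert m.r_peak == m.i_peak / m.tau_peak  # stored exactly

    def test_dropout_straddling_release_excludes(self):
        trace, ev, _ = gen_cuff_trace(CuffSimConfig(noise_sd=0.0))
        v = trace.values.copy()
        i0, i1 = trace.window_indices(ev.cuff_release_t - 1.0,
                                      ev.cuff_release_t + 2.5)
        v[i0:i1] = np.nan
        with pytest.raises(ExclusionError):
            analyze_cuff(trace.with_values(v), ev)

    def test_constant_trace_slope_zero_reox_undefined(self):
        trace = make_trace([65.0] * 4200)
        ev = ProtocolEvents(cuff_inflate_t=60.0, cuff_release_t=240.0)
        m = analyze_cuff(trace, ev)
        assert m.occlusion_slope == pytest.approx(0.0, abs=1e-12)
        assert math.isnan(m.tau_peak) and math.isnan(m.i_peak)
        assert math.isnan(m.r_peak)

    def test_missing_release_event_rejected(self):
        trace = make_trace([65.0] * 4200)
        with pytest.raises(ValueError):
            analyze_cuff(trace, ProtocolEvents(cuff_inflate_t=60.0))

    def test_desat_auc_matches_triangle_area(self):
        # linear desaturation: area between baseline and signal = s*T^2/2
        trace, ev, _ = gen_cuff_trace(CuffSimConfig(noise_sd=0.0))
        m = analyze_cuff(trace, ev)
        assert m.desat_auc == pytest.approx(0.06 * 180.0 ** 2 / 2.0, rel=0.01)

    def test_noisy_tau_recovery_median_error(self):
        """Median |tau-hat - 0.9943 tau|/tau < 10% at noise SD 0.5%."""
        errs = []
        for tau_true in (8.0, 12.0, 16.0):
            for seed in range(67):
                trace, ev, _ = gen_cuff_trace(
                    CuffSimConfig(tau_true=tau_true, noise_sd=0.5, seed=seed))
                m = analyze_cuff(trace, ev)
                errs.append(abs(m.tau_peak - LN037 * tau_true) / tau_true)
        assert np.median(errs) < 0.10

    def test_rep10s_increases_with_increment(self):
        """For fixed tau, a larger increment recovers faster over 10 s."""
        rates = []
        for slope in (-0.05, -0.07, -0.09):
            trace, ev, _ = gen_cuff_trace(
                CuffSimConfig(desat_slope=slope, noise_sd=0.0))
            rates.append(analyze_cuff(trace, ev).rep10s)
        assert rates[0] < rates[1] < rates[2]


class TestAnalyzeSse:
    def test_noiseless_round_trip(self):
        cfg = SseSimConfig(rec_tau_true=12.0, drop_pct=6.0, onset_tau_s=10.0,
                           noise_sd=0.0)
        trace, ev, truth = gen_sse_trace(cfg)
        m = analyze_sse(trace, ev)
        assert m.baseline_smo2 == pytest.approx(68.0, abs=1e-6)
        assert m.i_bl == pytest.approx(truth["i_true_bl"], abs=0.1)
        assert m.tau_bl == pytest.approx(12.0 * LN037, abs=0.15)
        assert m.r_bl == m.i_bl / m.tau_bl

    def test_zero_drop_recovery_undefined(self):
        trace, ev, _ = gen_sse_trace(SseSimConfig(drop_pct=0.0, noise_sd=0.0))
        m = analyze_sse(trace, ev)
        assert math.isnan(m.tau_bl) and math.isnan(m.r_bl)

    def test_pre_recovery_is_last_10s_exercise_mean(self):
        trace, ev, _ = gen_sse_trace(SseSimConfig(noise_sd=0.0))
        m = analyze_sse(trace, ev)
        from muscleox import window_mean
        assert m.pre_recovery_smo2 == pytest.approx(
            window_mean(trace, ev.exercise_end_t - 10.0, ev.exercise_end_t))
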