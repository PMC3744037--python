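import math

import numpy as np
import pytest

from lymphnir import (AnalysisConfig, Segment, classify_dominance, define_segments,
                      detect_arrival, detect_packets, detrend, packet_frequency,
                      packet_velocity, preset, simulate_trace, transport_time)
from lymphnir.packets import ArrivalResult, analyze_session
from lymphnir.synth import session_rois, simulate_video

from conftest import gaussian_pulse_trace, make_trace


class TestArrival:
    def test_sustained_step_crossing(self):
        # baseline 100 for the first 10 s, step to 130 at t=85 held thereafter;
        # threshold = max(120, 100 + 5*sd) = 120, crossed and sustained at 85 s
        dt = 0.5
        t = np.arange(0, 200, dt)
        v = np.where(t >= 85.0, 130.0, 100.0)
        tr = make_trace(v, dt_s=dt, background_mean=100.0, background_sd=0.5)
        res = detect_arrival(tr)
        assert res.detected
        assert res.baseline == pytest.approx(100.0)
        assert res.threshold == pytest.approx(120.0)
        assert res.arrival_time_s == pytest.approx(85.0, abs=dt)

    def test_flat_trace_undetected(self):
        tr = make_trace([100.0] * 100, dt_s=0.5, background_sd=1.0)
        res = detect_arrival(tr)
        assert not res.detected and math.isnan(res.arrival_time_s)

    def test_brief_spike_does_not_trigger(self):
        dt = 0.5
        v = np.full(100, 100.0)
        v[40] = 200.0  # single-sample spike, not sustained for 1 s
        res = detect_arrival(make_trace(v, dt_s=dt, background_sd=1.0))
        assert not res.detected

    def test_short_trace_is_error(self):
        with pytest.raises(ValueError, match="baseline"):
            detect_arrival(make_trace([1.0] * 5, dt_s=0.5))

    def test_simulated_arrival_within_two_seconds(self):
        cfg = preset("healthy", seed=42, duration_s=260)
        for vessel in cfg.vessels:
            tr, gt = simulate_trace(cfg, vessel)
            res = detect_arrival(tr)
            assert res.detected
            assert abs(res.arrival_time_s - gt.arrival_time_s[vessel]) <= 2.0


class TestTransportTime:
    def test_direct(self):
        assert transport_time(ArrivalResult(85.0, 100, 120, True)) == 85.0

    def test_recording_offset_bookkeeping(self):
        # recording started 30 s after injection; arrival at recording-time 55 s
        assert transport_time(ArrivalResult(55.0, 100, 120, True), t0_s=30.0) == 85.0

    def test_undetected_is_missing_not_zero(self):
        with pytest.raises(ValueError):
            transport_time(ArrivalResult(math.nan, 100, 120, False))


class TestSegments:
    def test_standard_layout(self):
        a, s = define_segments(ArrivalResult(85.0, 0, 0, True), 1200.0)
        assert (a.start_s, a.end_s) == (145.0, 245.0)
        assert (s.start_s, s.end_s) == (600.0, 700.0)
        assert not a.flags and not s.flags

    def test_late_arrival_overlaps_steady(self):
        a, s = define_segments(ArrivalResult(560.0, 0, 0, True), 1200.0)
        assert (a.start_s, a.end_s) == (620.0, 720.0)
        assert "overlap" in a.flags and "overlap" in s.flags

    def test_arrival_beyond_recording_is_error(self):
        with pytest.raises(ValueError):
            define_segments(ArrivalResult(1150.0, 0, 0, True), 1200.0)

    def test_truncation_is_flagged(self):
        a, _ = define_segments(ArrivalResult(85.0, 0, 0, True), 200.0)
        assert a.end_s == 200.0 and "truncated" in a.flags


class TestDetrend:
    def test_constant_trace_gives_zeros(self):
        det = detrend(make_trace([42.0] * 200, dt_s=0.5), window_s=10.0)
        np.testing.assert_allclose(det.values, 0.0, atol=1e-12)

    def test_linear_ramp_leaves_no_spurious_peaks(self):
        dt = 0.1
        t = np.arange(0, 120, dt)
        tr = make_trace(5.0 * t, dt_s=dt, background_sd=1.0)
        det = detrend(tr, window_s=30.0)
        seg = Segment("arrival", 20.0, 100.0)
        assert detect_packets(det, seg) == []

    def test_simulated_pulse_amplitude_preserved(self):
        cfg = preset("healthy", seed=7, duration_s=260)
        cfg.vessels["dominant"] = type(cfg.vessels["dominant"])(20.0, 4.0, 2.4)
        tr, gt = simulate_trace(cfg, "dominant")
        det = detrend(tr)
        seg = Segment("arrival", 80.0, 240.0)
        packets = detect_packets(det, seg)
        assert packets, "expected detectable packets"
        amps = np.array([p.amplitude for p in packets])
        assert abs(amps.mean() - cfg.packet_amplitude) <= 0.15 * cfg.packet_amplitude

    def test_too_small_window_is_error(self):
        with pytest.raises(ValueError):
            detrend(make_trace([1.0] * 50, dt_s=0.5), window_s=0.5)


class TestDetectPackets:
    def test_tiny_example_exhaustively_verifiable(self):
        # samples at 1-s spacing, prominence floor 3, min separation 2 s
        tr = make_trace([0, 0, 1, 5, 1, 0, 6, 1, 0], dt_s=1.0, background_sd=3.0)
        cfg = AnalysisConfig(peak_min_prominence_sd=1.0, peak_dynamic_range_frac=0.0,
                             peak_min_separation_s=2.0)
        peaks = detect_packets(tr, Segment("arrival", 0.0, 8.0), cfg)
        assert [p.peak_time_s for p in peaks] == [3.0, 6.0]
        assert all(p.prominence > 0 and p.width_s > 0 for p in peaks)

    def test_flat_segment_gives_empty_list(self):
        tr = make_trace([0.0] * 50, dt_s=1.0, background_sd=1.0)
        assert detect_packets(tr, Segment("arrival", 0.0, 49.0)) == []

    def test_determinism(self):
        rng = np.random.default_rng(3)
        tr = make_trace(rng.normal(0, 1, 500), dt_s=0.5, background_sd=0.3)
        seg = Segment("arrival", 0.0, 249.0)
        a = detect_packets(tr, seg)
        b = detect_packets(tr, seg)
        assert [p.peak_time_s for p in a] == [p.peak_time_s for p in b]

    def test_noise_does_not_inflate_counts_in_expectation(self):
        counts = {}
        for noise in (2.0, 10.0):
            n = []
            for seed in range(30):
                cfg = preset("healthy", seed=seed, duration_s=260, noise_sd=noise)
                tr, _ = simulate_trace(cfg, "dominant")
                seg = Segment("arrival", 120.0, 220.0)
                n.append(len(detect_packets(detrend(tr), seg)))
            counts[noise] = np.mean(n)
        assert counts[10.0] <= counts[2.0] + 0.5


class TestFrequency:
    def test_arithmetic(self):
        seg = Segment("arrival", 0.0, 100.0)
        packets = [object()] * 12
        assert packet_frequency(packets, seg) == pytest.approx(7.2)
        assert packet_frequency([], seg) == 0.0

    def test_zero_duration_is_error(self):
        with pytest.raises(ValueError):
            packet_frequency([], Segment("arrival", 5.0, 5.0))


class TestVelocity:
    def test_slope_from_known_front_times(self):
        # fronts 10, 11, 12 s at positions 2, 6, 10 mm -> 4 mm/s
        subs = [gaussian_pulse_trace([tk], axial_mm=x)
                for tk, x in ((10.0, 2.0), (11.0, 6.0), (12.0, 10.0))]
        est = packet_velocity(subs, Segment("arrival", 5.0, 20.0))
        assert est.mm_s == pytest.approx(4.0, rel=0.02)
        assert est.n_used == 1

    def test_simultaneous_fronts_are_discarded(self):
        subs = [gaussian_pulse_trace([10.0], axial_mm=x) for x in (2.0, 6.0, 10.0)]
        est = packet_velocity(subs, Segment("arrival", 5.0, 20.0))
        assert math.isnan(est.mm_s) and est.n_discarded == 1

    def test_too_few_subrois_is_error(self):
        subs = [gaussian_pulse_trace([10.0], axial_mm=x) for x in (2.0, 10.0)]
        with pytest.raises(ValueError):
            packet_velocity(subs, Segment("arrival", 5.0, 20.0))

    def test_narrow_span_is_error(self):
        subs = [gaussian_pulse_trace([10.0], axial_mm=x) for x in (2.0, 3.0, 4.0)]
        with pytest.raises(ValueError, match="span"):
            packet_velocity(subs, Segment("arrival", 5.0, 20.0))


class TestDominance:
    @staticmethod
    def _arr(t):
        return ArrivalResult(t, 100.0, 120.0, detected=not math.isnan(t))

    def test_earlier_arrival_wins(self):
        traces = {"a": make_trace([1.0] * 30, dt_s=10.0), "b": make_trace([1.0] * 30, dt_s=10.0)}
        res = classify_dominance({"a": self._arr(60.0), "b": self._arr(85.0)}, traces)
        assert res.label == "a" and not res.tie_break_used

    def test_identical_traces_tie_break_deterministic(self):
        traces = {"a": make_trace([1.0] * 300, dt_s=1.0), "b": make_trace([1.0] * 300, dt_s=1.0)}
        res = classify_dominance({"a": self._arr(50.0), "b": self._arr(50.0)}, traces)
        assert res.label == "a"
        assert res.tie_break_used and "tie_unresolved_roi_order" in res.flags

    def test_tie_break_prefers_brighter_vessel(self):
        traces = {"a": make_trace([1.0] * 300, dt_s=1.0), "b": make_trace([2.0] * 300, dt_s=1.0)}
        res = classify_dominance({"a": self._arr(50.0), "b": self._arr(50.0)}, traces)
        assert res.label == "b" and res.tie_break_used

    def test_single_detected_vessel_is_dominant(self):
        traces = {"a": make_trace([1.0] * 30, dt_s=10.0), "b": make_trace([1.0] * 30, dt_s=10.0)}
        res = classify_dominance({"a": self._arr(math.nan), "b": self._arr(90.0)}, traces)
        assert res.label == "b" and "single_vessel_detected" in res.flags

    def test_neither_detected_is_error(self):
        traces = {"a": make_trace([1.0] * 30, dt_s=10.0), "b": make_trace([1.0] * 30, dt_s=10.0)}
        with pytest.raises(ValueError):
            classify_dominance({"a": self._arr(math.nan), "b": self._arr(math.nan)}, traces)


class TestTimeShiftEquivariance:
    def test_arrival_and_frequency_shift_consistently(self):
        cfg = preset("healthy", seed=9, duration_s=260)
        tr, _ = simulate_trace(cfg, "dominant")
        shift = 37.0
        arr0 = detect_arrival(tr)
        arr1 = detect_arrival(tr.shifted(shift))
        assert arr1.arrival_time_s == pytest.approx(arr0.arrival_time_s + shift, abs=1e-9)

        det0, det1 = detrend(tr), detrend(tr.shifted(shift))
        seg0 = Segment("arrival", 120.0, 220.0)
        seg1 = Segment("arrival", 120.0 + shift, 220.0 + shift)
        f0 = packet_frequency(detect_packets(det0, seg0), seg0)
        f1 = packet_frequency(detect_packets(det1, seg1), seg1)
        assert f1 == f0


class TestAnalyzeSession:
    def test_no_fluorescence_degrades_gracefully(self):
        cfg = preset("healthy", seed=1, duration_s=100, baseline_plateau=0.0,
                     packet_amplitude=0.0)
        stack, _ = simulate_video(cfg)
        res = analyze_session(stack, session_rois(cfg))
        assert "no_arrival_detected" in res.flags
        for m in res.metrics.values():
            assert math.isnan(m.transport_time_s)
            assert "arrival_not_detected" in m.flags

    def test_week0_fixed_dominance(self):
        acfg = AnalysisConfig(steady_start_s=150.0)
        cfg0 = preset("healthy", seed=21, duration_s=260)
        stack0, _ = simulate_video(cfg0)
        res0 = analyze_session(stack0, session_rois(cfg0), acfg, animal_id="r1", week=0)
        assert res0.dominance_source == "this_session"

        cfg1 = preset("icg_week2", seed=22, duration_s=400)
        stack1, _ = simulate_video(cfg1)
        res1 = analyze_session(stack1, session_rois(cfg1), acfg, week0_result=res0,
                               animal_id="r1", week=1)
        assert res1.dominance_source == "week0_fixed"
        assert res1.dominant_label == res0.dominant_label
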