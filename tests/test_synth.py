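import math
from dataclasses import replace

import numpy as np
import pytest

from lymphnir import (SimConfig, VesselParams, preset, simulate_node_image,
                      simulate_retention_series, simulate_trace, simulate_video)
from lymphnir.synth import PRESET_NAMES, retention_rois, session_rois
from lymphnir.traces import extract_trace


def two_vessels(arrival=(20.0, 30.0), rate=(4.0, 4.0), vel=(2.4, 1.8)):
    return {
        "dominant": VesselParams(arrival[0], rate[0], vel[0]),
        "nondominant": VesselParams(arrival[1], rate[1], vel[1]),
    }


class TestTraceSimulation:
    def test_null_process_gives_constant_background(self):
        cfg = SimConfig(duration_s=60.0, noise_sd=0.0, baseline_plateau=0.0,
                        vessels=two_vessels(rate=(0.0, 0.0)))
        tr, gt = simulate_trace(cfg, "dominant")
        np.testing.assert_allclose(tr.values, cfg.background_level)
        assert gt.packet_times_s["dominant"].size == 0

    def test_single_pulse_peaks_at_packet_time(self):
        # sparse noiseless pulses: trace maximum near each packet within half a frame
        cfg = SimConfig(duration_s=600.0, noise_sd=0.0, baseline_plateau=0.0,
                        vessels=two_vessels(rate=(0.5, 0.0)), seed=4)
        tr, gt = simulate_trace(cfg, "dominant")
        times = gt.packet_times_s["dominant"]
        assert times.size >= 1
        for tk in times:
            win = (tr.times_s > tk - 2.0) & (tr.times_s < tk + 2.0)
            t_max = tr.times_s[win][np.argmax(tr.values[win])]
            assert abs(t_max - tk) <= cfg.frame_interval_s / 2 + 1e-9

    def test_renewal_counts_match_rate(self):
        # gamma-renewal counting: N ~ mean (T*rate/60), var ~ mean/shape
        rate, t_arr, dur = 6.0, 20.0, 1200.0
        expect = (dur - t_arr) * rate / 60.0
        sd = math.sqrt(expect / 4.0)
        counts = []
        for seed in range(50):
            cfg = SimConfig(duration_s=dur, seed=seed,
                            vessels=two_vessels(arrival=(t_arr, 30.0), rate=(rate, 0.0)))
            _, gt = simulate_trace(cfg, "dominant")
            n = gt.packets_in("dominant", t_arr, dur)
            counts.append(n)
            assert abs(n - expect) <= 3.0 * sd + 2.0
        assert abs(np.mean(counts) - expect) <= 3.0 * sd / math.sqrt(len(counts)) + 1.0

    def test_packet_times_respect_arrival_invariant(self):
        cfg = SimConfig(duration_s=300.0, seed=8, vessels=two_vessels(rate=(10.0, 10.0)))
        for vessel in cfg.vessels:
            _, gt = simulate_trace(cfg, vessel)
            times = gt.packet_times_s[vessel]
            assert np.all(np.diff(times) > 0)
            assert times.min() >= gt.arrival_time_s[vessel]

    def test_duration_shorter_than_arrival_rejected(self):
        cfg = SimConfig(duration_s=25.0, vessels=two_vessels(arrival=(20.0, 30.0)))
        with pytest.raises(ValueError, match="arrival"):
            simulate_trace(cfg, "nondominant")

    def test_identical_seed_bit_identical(self):
        cfg = SimConfig(duration_s=120.0, seed=13, vessels=two_vessels())
        tr1, gt1 = simulate_trace(cfg, "dominant")
        tr2, gt2 = simulate_trace(cfg, "dominant")
        np.testing.assert_array_equal(tr1.values, tr2.values)
        np.testing.assert_array_equal(gt1.packet_times_s["dominant"],
                                      gt2.packet_times_s["dominant"])


class TestVideoSimulation:
    def test_zero_packets_zero_noise_is_flat_background(self):
        cfg = SimConfig(duration_s=15.0, noise_sd=0.0, baseline_plateau=0.0,
                        vessels=two_vessels(arrival=(10.0, 12.0), rate=(0.0, 0.0)))
        stack, _ = simulate_video(cfg)
        np.testing.assert_allclose(stack.frames, cfg.background_level)

    def test_single_packet_kinematics_two_points_four_mm_apart(self):
        # blob at 2 mm/s passes two axial positions 4 mm apart 2.0 s later
        cfg = SimConfig(duration_s=120.0, noise_sd=0.0, baseline_plateau=0.0, seed=2,
                        vessels=two_vessels(arrival=(10.0, 11.0), rate=(0.6, 0.0),
                                            vel=(2.0, 2.0)))
        stack, gt = simulate_video(cfg)
        tk = gt.packet_times_s["dominant"][0]
        yc = cfg._vessel_rows()[0]
        x1, x2 = 30, 70  # pixels: 3 mm and 7 mm along the window
        t1 = stack.times_s[np.argmax(stack.frames[:, yc, x1])]
        t2 = stack.times_s[np.argmax(stack.frames[:, yc, x2])]
        assert t2 - t1 == pytest.approx(2.0, abs=2 * cfg.frame_interval_s)
        assert t1 == pytest.approx(tk + 3.0 / 2.0, abs=0.2)

    def test_video_roi_trace_matches_trace_statistics(self):
        # same seed stream: packet count and mean pulse amplitude agree
        from lymphnir.packets import Segment, detect_packets, detrend

        cfg = SimConfig(duration_s=300.0, seed=5,
                        vessels=two_vessels(arrival=(20.0, 25.0), rate=(4.0, 0.0)))
        tr, gt_tr = simulate_trace(cfg, "dominant")
        stack, gt_vid = simulate_video(cfg)
        np.testing.assert_array_equal(gt_tr.packet_times_s["dominant"],
                                      gt_vid.packet_times_s["dominant"])
        rois = session_rois(cfg)
        vid_tr = extract_trace(stack, rois[0], rois[2])
        seg = Segment("arrival", 60.0, 280.0)
        p_trace = detect_packets(detrend(tr), seg)
        p_video = detect_packets(detrend(vid_tr), seg)
        assert abs(len(p_trace) - len(p_video)) <= 1
        amp_t = np.mean([p.amplitude for p in p_trace])
        amp_v = np.mean([p.amplitude for p in p_video])
        assert amp_v == pytest.approx(amp_t, rel=0.25)

    def test_vessel_rois_out_of_frame_rejected(self):
        cfg = SimConfig(frame_height_px=10, vessel_separation_px=12,
                        vessels=two_vessels())
        with pytest.raises(ValueError, match="frame"):
            simulate_video(cfg)

    def test_identical_seed_bit_identical(self):
        cfg = SimConfig(duration_s=40.0, seed=3, vessels=two_vessels(arrival=(10., 12.)))
        s1, _ = simulate_video(cfg)
        s2, _ = simulate_video(cfg)
        np.testing.assert_array_equal(s1.frames, s2.frames)


class TestRetention:
    def test_day0_snr_closed_form(self):
        # amplitude/noise ratio 20 -> 26.02 dB under the 20*log10 convention
        cfg = SimConfig()
        _, gt = simulate_retention_series(cfg)
        assert gt.snr_db_by_day[0] == pytest.approx(26.02, abs=0.01)

    def test_ground_truth_snr_monotone_decay(self):
        _, gt = simulate_retention_series(SimConfig())
        snrs = [gt.snr_db_by_day[d] for d in sorted(gt.snr_db_by_day)]
        assert all(a > b for a, b in zip(snrs, snrs[1:]))

    def test_default_crossing_between_day_14_and_21(self):
        _, gt = simulate_retention_series(SimConfig())
        assert 14.0 < gt.retention_crossing_day < 21.0

    def test_rois_are_disjoint(self):
        cfg = SimConfig()
        inj, bg = retention_rois(cfg)
        n = cfg.retention_image_px
        assert not np.any(inj.mask(n, n) & bg.mask(n, n))


class TestNodeImages:
    def test_week0_any_group_is_baseline_area(self):
        cfg = SimConfig()
        _, a_icg = simulate_node_image(0, "icg", cfg)
        _, a_ctl = simulate_node_image(0, "control", cfg)
        baseline = math.pi * cfg.node_axes_mm[0] * cfg.node_axes_mm[1]
        assert a_icg == pytest.approx(baseline)
        assert a_ctl == pytest.approx(baseline)

    def test_week1_percent_change_is_350(self):
        from lymphnir import percent_change
        cfg = SimConfig()
        _, a0 = simulate_node_image(0, "icg", cfg)
        _, a1 = simulate_node_image(1, "icg", cfg)
        assert percent_change(a0, a1) == pytest.approx(350.0)

    def test_control_flat_across_weeks(self):
        cfg = SimConfig()
        areas = [simulate_node_image(w, "control", cfg)[1] for w in (0, 1, 2, 4)]
        assert all(a == pytest.approx(areas[0]) for a in areas)

    def test_noiseless_unblurred_ellipse_recovered_exactly(self):
        from lymphnir import node_area
        cfg = SimConfig(node_texture_sd=0.0, node_blur_sigma_px=0.0, node_noise_sd=0.0)
        img, true_area = simulate_node_image(2, "icg", cfg)
        est = node_area(img, cfg.node_pixel_size_mm)
        # within a one-pixel boundary ring of the analytic pi*a*b
        a = cfg.node_axes_mm[0] * math.sqrt(3.0) / cfg.node_pixel_size_mm
        b = cfg.node_axes_mm[1] * math.sqrt(3.0) / cfg.node_pixel_size_mm
        ring = math.pi * ((a + 1) * (b + 1) - a * b) * cfg.node_pixel_size_mm**2
        assert abs(est - true_area) <= ring

    def test_invalid_week_and_group_rejected(self):
        cfg = SimConfig()
        with pytest.raises(ValueError):
            simulate_node_image(3, "icg", cfg)
        with pytest.raises(ValueError):
            simulate_node_image(1, "saline", cfg)


class TestPresets:
    def test_healthy_arrival_offset_at_least_20s(self):
        cfg = preset("healthy")
        offset = (cfg.vessels["nondominant"].arrival_time_s
                  - cfg.vessels["dominant"].arrival_time_s)
        assert offset >= 20.0

    def test_healthy_dominant_arrives_first(self):
        cfg = preset("healthy")
        assert (cfg.vessels["dominant"].arrival_time_s
                < cfg.vessels["nondominant"].arrival_time_s)

    def test_gtno_sixfold_nondominant_transport(self):
        ratio = (preset("gtno").vessels["nondominant"].arrival_time_s
                 / preset("healthy").vessels["nondominant"].arrival_time_s)
        assert ratio == pytest.approx(6.0)

    def test_gtno_slows_both_vessels(self):
        g, h = preset("gtno"), preset("healthy")
        for v in ("dominant", "nondominant"):
            assert g.vessels[v].packet_rate_per_min < h.vessels[v].packet_rate_per_min
            assert g.vessels[v].packet_velocity_mm_s < h.vessels[v].packet_velocity_mm_s

    def test_icg_week2_degrades_only_nondominant(self):
        w2, h = preset("icg_week2"), preset("healthy")
        assert w2.vessels["dominant"] == h.vessels["dominant"]
        assert w2.vessels["nondominant"].packet_rate_per_min < h.vessels["nondominant"].packet_rate_per_min

    def test_control_equals_healthy_field_by_field(self):
        c, h = preset("control"), preset("healthy")
        assert c.vessels == h.vessels
        c2 = replace(c, vessels=h.vessels)
        assert c2 == replace(h, vessels=h.vessels)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            preset("lymphedema")
        assert set(PRESET_NAMES) >= {"healthy", "gtno", "icg_week1", "icg_week2"}
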