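"""Core lymphatic-function quantification from intensity traces.

A collecting lymphatic vessel propels discrete boluses ("packets") of lymph
through the imaging window; each packet appears as a transient pulse riding
on a slowly rising free-flow baseline.  This module measures the three
function metrics per vessel and session:

* **transport time** — seconds from tracer injection until fluorescence
  arrival at the window (a sustained 20% rise above the pre-arrival
  baseline),
* **packet frequency** — packets per minute within a 100-s analysis
  segment (local prominence maxima on a running-median detrended trace),
* **packet velocity** — mm/s from least-squares regression of packet front
  times across axial sub-ROIs (median over packets per segment),

and classifies the two vessels as dominant (earlier fluorescence arrival)
versus non-dominant.  In longitudinal designs the dominance labels are
fixed from the week-0 session.

Arrival threshold
-----------------
The nominal criterion is a 20% intensity rise over the pre-arrival
baseline.  A bare relative threshold is ill-posed when the baseline is near
zero, so the working threshold is ``max(1.2 * baseline,
baseline + 5 * background_sd)`` and must be exceeded continuously for 1 s.
Missing metrics are explicit NaNs, never zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal

from .config import AnalysisConfig
from .io import FrameStack, Roi, validate_session_rois
from .traces import (IntensityTrace, extract_trace, sub_roi_axial_midpoints_mm,
                     subdivide_vessel_roi)

__all__ = [
    "ArrivalResult", "Segment", "Packet", "VesselMetrics", "SessionResult",
    "VelocityEstimate", "DominanceResult",
    "detect_arrival", "transport_time", "define_segments", "detrend",
    "detect_packets", "packet_frequency", "packet_velocity",
    "classify_dominance", "analyze_session",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ArrivalResult:
    """Outcome of fluorescence-arrival detection for one vessel trace."""

    arrival_time_s: float
    baseline: float
    threshold: float
    detected: bool


@dataclass
class Segment:
    """A named analysis window, default length 100 s."""

    name: str  # "arrival" | "steady_state"
    start_s: float
    end_s: float
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end_s < self.start_s:
            raise ValueError("segment end before start")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class Packet:
    """One detected lymph packet (transient intensity pulse)."""

    peak_time_s: float
    amplitude: float
    prominence: float
    width_s: float
    front_times_s: list[float] | None = None  # per-sub-ROI crossing times


@dataclass
class VesselMetrics:
    """The three function metrics for one vessel in one session.

    Frequencies/velocities are resolved per analysis segment; NaN marks a
    metric that could not be measured (e.g. arrival never detected).
    """

    transport_time_s: float = math.nan
    freq_arrival: float = math.nan
    freq_steady: float = math.nan
    vel_arrival: float = math.nan
    vel_steady: float = math.nan
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {
            "transport_time_s": self.transport_time_s,
            "freq_arrival_per_min": self.freq_arrival,
            "freq_steady_per_min": self.freq_steady,
            "vel_arrival_mm_s": self.vel_arrival,
            "vel_steady_mm_s": self.vel_steady,
        }


@dataclass
class VelocityEstimate:
    """Median packet velocity over a segment with bookkeeping."""

    mm_s: float
    n_used: int = 0
    n_discarded: int = 0

    def __float__(self) -> float:
        return float(self.mm_s)


@dataclass
class DominanceResult:
    label: str
    tie_break_used: bool = False
    flags: list[str] = field(default_factory=list)


@dataclass
class SessionResult:
    """Paired vessel metrics for one imaging session plus dominance."""

    animal_id: str
    week: int
    group: str
    metrics: dict[str, VesselMetrics]  # keyed by vessel ROI label
    dominant_label: str
    dominance_source: str  # "this_session" | "week0_fixed"
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.dominant_label not in self.metrics:
            raise ValueError("dominant_label must name one of the vessels")
        if self.week > 0 and self.dominance_source != "week0_fixed":
            raise ValueError("follow-up sessions must carry week0_fixed dominance")

    def role(self, label: str) -> str:
        return "dominant" if label == self.dominant_label else "nondominant"

    def by_role(self) -> dict[str, VesselMetrics]:
        return {self.role(lbl): m for lbl, m in self.metrics.items()}

    def to_rows(self) -> list[dict]:
        rows = []
        for lbl, m in self.metrics.items():
            row = {
                "animal_id": self.animal_id,
                "week": self.week,
                "group": self.group,
                "vessel_label": lbl,
                "vessel_role": self.role(lbl),
                "dominance_source": self.dominance_source,
                "flags": ";".join(self.flags + m.flags),
            }
            row.update(m.as_dict())
            rows.append(row)
        return rows


# ---------------------------------------------------------------------------
# arrival and segments


def detect_arrival(trace: IntensityTrace, config: AnalysisConfig | None = None) -> ArrivalResult:
    """Detect fluorescence arrival as a sustained rise above baseline.

    Baseline is the median of the first 10 s of the trace; the threshold is
    ``max((1 + rise) * baseline, baseline + k * background_sd)`` and must be
    exceeded for at least ``arrival_sustain_s`` of consecutive samples.
    """
    cfg = config or AnalysisConfig()
    t = trace.times_s
    dt = trace.dt_s
    base_sel = t < t[0] + cfg.baseline_window_s
    if (t[-1] - t[0]) < cfg.baseline_window_s:
        raise ValueError("trace shorter than the baseline window")
    baseline = float(np.median(trace.values[base_sel]))
    threshold = max(
        (1.0 + cfg.arrival_rise_fraction) * baseline,
        baseline + cfg.arrival_noise_floor_sd * trace.background_sd,
    )
    above = trace.values > threshold
    n_sustain = max(1, int(round(cfg.arrival_sustain_s / dt)))
    idx = _first_sustained(above, n_sustain)
    if idx is None:
        return ArrivalResult(math.nan, baseline, threshold, detected=False)
    return ArrivalResult(float(t[idx]), baseline, threshold, detected=True)


def _first_sustained(above: np.ndarray, n: int) -> int | None:
    if n <= 1:
        hits = np.flatnonzero(above)
        return int(hits[0]) if hits.size else None
    ok = sliding_window_view(above, n).all(axis=1)
    hits = np.flatnonzero(ok)
    return int(hits[0]) if hits.size else None


def transport_time(arrival: ArrivalResult, t0_s: float = 0.0) -> float:
    """Transport time in seconds since injection.

    Traces built from a :class:`FrameStack` already carry absolute times
    (``t0_s`` folded into the timestamps); pass ``t0_s`` only for traces
    recorded in recording-relative time.
    """
    if not arrival.detected:
        raise ValueError("arrival not detected; transport time is missing, not zero")
    return arrival.arrival_time_s + t0_s


def define_segments(arrival: ArrivalResult, trace_end_s: float,
                    config: AnalysisConfig | None = None) -> tuple[Segment, Segment]:
    """The two analysis windows for one vessel.

    Arrival segment: ``[t_arr + 60, t_arr + 160]`` (anchored per vessel).
    Steady-state segment: ``[600, 700]`` seconds post-injection (anchored to
    the injection, exactly as specified, even when a late arrival makes the
    two overlap — overlap is flagged, never silently shifted).
    """
    cfg = config or AnalysisConfig()
    if not arrival.detected:
        raise ValueError("cannot define segments without a detected arrival")
    a_start = arrival.arrival_time_s + cfg.arrival_segment_delay_s
    a_end = a_start + cfg.segment_length_s
    if a_start >= trace_end_s:
        raise ValueError("arrival segment lies entirely beyond the recording")
    arrival_seg = Segment("arrival", a_start, min(a_end, trace_end_s))
    if a_end > trace_end_s:
        arrival_seg.flags.append("truncated")

    s_start = cfg.steady_start_s
    s_end = s_start + cfg.segment_length_s
    steady = Segment("steady_state", min(s_start, trace_end_s), min(s_end, trace_end_s))
    if s_start >= trace_end_s:
        steady.flags.append("beyond_recording")
    elif s_end > trace_end_s:
        steady.flags.append("truncated")

    if arrival_seg.start_s < steady.end_s and steady.start_s < arrival_seg.end_s:
        arrival_seg.flags.append("overlap")
        steady.flags.append("overlap")
    return arrival_seg, steady


# ---------------------------------------------------------------------------
# detrending and packet detection


def detrend(trace: IntensityTrace, window_s: float | None = None,
            config: AnalysisConfig | None = None) -> IntensityTrace:
    """Subtract a running-median baseline (default window 30 s).

    The running median tracks the slow free-flow baseline while ignoring
    the short packet pulses, so the residual isolates the pulsatile
    component around zero.  Background statistics are preserved for
    downstream prominence floors.
    """
    cfg = config or AnalysisConfig()
    win = cfg.detrend_window_s if window_s is None else window_s
    dt = trace.dt_s
    if win <= 2 * dt:
        raise ValueError("detrend window must exceed twice the sample spacing")
    baseline = _running_median(trace.values, max(3, int(round(win / dt)) | 1))
    return replace(trace, values=trace.values - baseline)


def _running_median(x: np.ndarray, win: int) -> np.ndarray:
    """Edge-padded running median, evaluated on a decimated grid and
    linearly interpolated back (the baseline is slow by construction)."""
    n = x.size
    win = min(win, 2 * n - 1) | 1
    pad = win // 2
    xp = np.pad(x, pad, mode="edge")
    sw = sliding_window_view(xp, win)
    stride = max(1, win // 120)
    idx = np.arange(0, n, stride)
    if idx[-1] != n - 1:
        idx = np.append(idx, n - 1)
    med = np.median(sw[idx], axis=1)
    if stride == 1:
        return med
    return np.interp(np.arange(n), idx, med)


def detect_packets(trace: IntensityTrace, segment: Segment,
                   config: AnalysisConfig | None = None) -> list[Packet]:
    """Detect packet pulses in a *detrended* trace within a segment.

    Packets are local maxima with prominence at least
    ``max(k * background_sd, f * segment dynamic range)`` and minimum peak
    separation ``peak_min_separation_s`` (higher peaks win ties).  A short
    boxcar pre-smoothing (``peak_smooth_s``, well below the pulse width)
    suppresses noise-induced splitting of one pulse into several maxima, so
    raising the noise level cannot inflate counts above the prominence
    floor.  Deterministic for fixed input; an empty list is a valid result.
    """
    cfg = config or AnalysisConfig()
    sel = trace.slice(segment.start_s, segment.end_s)
    x = trace.values[sel]
    t = trace.times_s[sel]
    if x.size < 3:
        return []
    dt = float(np.median(np.diff(t)))
    if cfg.peak_smooth_s > 0:
        x = _boxcar_smooth(x, max(1, int(round(cfg.peak_smooth_s / dt))) | 1)
    floor = cfg.peak_min_prominence_sd * trace.background_sd
    dyn = cfg.peak_dynamic_range_frac * float(x.max() - x.min())
    prominence = max(floor, dyn)
    if prominence <= 0:
        prominence = np.finfo(float).tiny
    distance = max(1, int(round(cfg.peak_min_separation_s / dt)))
    peaks, props = signal.find_peaks(x, distance=distance, prominence=prominence)
    if peaks.size == 0:
        return []
    widths = signal.peak_widths(x, peaks, rel_height=0.5)[0] * dt
    return [
        Packet(
            peak_time_s=float(t[p]),
            amplitude=float(x[p]),
            prominence=float(props["prominences"][k]),
            width_s=float(max(widths[k], dt)),
        )
        for k, p in enumerate(peaks)
    ]


def _boxcar_smooth(x: np.ndarray, win: int) -> np.ndarray:
    if win <= 1 or x.size < 3:
        return x
    win = min(win, 2 * x.size - 1) | 1
    pad = win // 2
    xp = np.pad(x, pad, mode="edge")
    kernel = np.full(win, 1.0 / win)
    return np.convolve(xp, kernel, mode="valid")


def packet_frequency(packets: Sequence[Packet], segment: Segment) -> float:
    """Packets per minute over the segment."""
    if segment.duration_s <= 0:
        raise ValueError("segment duration must be positive")
    return 60.0 * len(packets) / segment.duration_s


# ---------------------------------------------------------------------------
# velocimetry


def packet_velocity(sub_traces: Sequence[IntensityTrace], segment: Segment,
                    config: AnalysisConfig | None = None,
                    positions_mm: Sequence[float] | None = None,
                    predetrended: bool = False) -> VelocityEstimate:
    """Packet velocity (mm/s) by front-time regression across sub-ROIs.

    For each packet detected in the reference (middle) sub-trace, the front
    time at every other sub-ROI is the parabolically interpolated peak time
    of its pulse, found by walking outward from the middle within a search
    window bounded by ``velocity_min_mm_s``.  Velocity is the least-squares
    slope of axial position versus front time; the per-segment value is the
    median over packets.  Packets with non-monotone fronts, fit R² below
    ``velocity_r2_min``, or implied speed above ``velocity_max_mm_s``
    (infinite-velocity guard) are discarded and counted.
    """
    cfg = config or AnalysisConfig()
    if len(sub_traces) < 3:
        raise ValueError("packet velocity needs >= 3 sub-ROIs")
    if positions_mm is None:
        positions_mm = [tr.axial_mm for tr in sub_traces]
        if any(p is None for p in positions_mm):
            raise ValueError("sub-traces lack axial positions")
    pos = np.asarray(positions_mm, dtype=float)
    if np.any(np.diff(pos) <= 0):
        raise ValueError("axial positions must be strictly increasing")
    if pos[-1] - pos[0] < 5.0:
        raise ValueError("sub-ROIs must span >= 5 mm of vessel")

    det = list(sub_traces) if predetrended else [detrend(tr, config=cfg) for tr in sub_traces]
    mid = len(det) // 2
    ref_packets = detect_packets(det[mid], segment, cfg)
    dt = det[mid].dt_s
    amp_floor = 3.0 * det[mid].background_sd

    speeds: list[float] = []
    n_discarded = 0
    for pk in ref_packets:
        fronts = _track_fronts(det, pos, mid, pk.peak_time_s, dt, cfg, amp_floor)
        v = _fit_front_velocity(fronts, dt, cfg)
        if v is None:
            n_discarded += 1
        else:
            speeds.append(v)
            pk.front_times_s = [t for _, t in fronts]
    if not speeds:
        return VelocityEstimate(math.nan, 0, n_discarded)
    return VelocityEstimate(float(np.median(speeds)), len(speeds), n_discarded)


def _track_fronts(det: list[IntensityTrace], pos: np.ndarray, mid: int,
                  t_ref: float, dt: float, cfg: AnalysisConfig,
                  amp_floor: float) -> list[tuple[float, float]]:
    """Front (position_mm, time_s) pairs for one packet, middle outward."""
    t_mid = _refine_peak(det[mid], t_ref, dt)
    fronts: dict[int, float] = {mid: t_mid}
    for direction in (+1, -1):
        anchor_i, anchor_t = mid, t_mid
        i = mid + direction
        while 0 <= i < len(det):
            dx = abs(pos[i] - pos[anchor_i])
            max_lag = dx / cfg.velocity_min_mm_s
            if direction > 0:
                window = (anchor_t + dt, anchor_t + max_lag)
            else:
                window = (anchor_t - max_lag, anchor_t - dt)
            hit = _window_front(det[i], window, amp_floor, direction)
            if hit is not None:
                fronts[i] = hit
                anchor_i, anchor_t = i, hit
            i += direction
    order = sorted(fronts)
    return [(float(pos[i]), fronts[i]) for i in order]


def _fit_front_velocity(fronts: list[tuple[float, float]], dt: float,
                        cfg: AnalysisConfig) -> float | None:
    if len(fronts) < 3:
        return None
    x = np.array([p for p, _ in fronts])
    t = np.array([t for _, t in fronts])
    if np.any(np.diff(t) <= 0):  # non-monotone front propagation
        return None
    if t[-1] - t[0] < dt:  # effectively simultaneous fronts
        return None
    slope, intercept = np.polyfit(t, x, 1)
    pred = slope * t + intercept
    ss_tot = float(np.sum((x - x.mean()) ** 2))
    r2 = 1.0 - float(np.sum((x - pred) ** 2)) / ss_tot if ss_tot > 0 else 0.0
    v = float(slope)
    if not np.isfinite(v) or v <= 0 or v > cfg.velocity_max_mm_s or r2 < cfg.velocity_r2_min:
        return None
    return v


def _refine_peak(trace: IntensityTrace, t_peak: float, dt: float) -> float:
    j = int(np.argmin(np.abs(trace.times_s - t_peak)))
    return _parabolic_time(trace, j, dt)


def _window_front(trace: IntensityTrace, window: tuple[float, float],
                  amp_floor: float, direction: int) -> float | None:
    """Front time of the matching pulse within a search window.

    Candidates are strict local maxima above the amplitude floor; the one
    nearest the anchor (earliest for distal walks, latest for proximal) is
    the same packet — farther candidates belong to neighbouring packets.
    """
    sel = np.flatnonzero(trace.slice(*window))
    if sel.size == 0:
        return None
    x = trace.values
    interior = sel[(sel > 0) & (sel < x.size - 1)]
    is_max = (x[interior] > x[interior - 1]) & (x[interior] > x[interior + 1])
    cand = interior[is_max & (x[interior] >= amp_floor)]
    if cand.size == 0:
        return None
    j = int(cand[0] if direction > 0 else cand[-1])
    return _parabolic_time(trace, j, trace.dt_s)


def _parabolic_time(trace: IntensityTrace, j: int, dt: float) -> float:
    """Sub-frame peak time via a parabola through the three samples at j."""
    x = trace.values
    if j <= 0 or j >= x.size - 1:
        return float(trace.times_s[j])
    denom = x[j - 1] - 2.0 * x[j] + x[j + 1]
    if denom >= 0:  # not a concave maximum
        return float(trace.times_s[j])
    delta = 0.5 * (x[j - 1] - x[j + 1]) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    return float(trace.times_s[j] + delta * dt)


# ---------------------------------------------------------------------------
# dominance and session composition


def classify_dominance(arrivals: Mapping[str, ArrivalResult],
                       traces: Mapping[str, IntensityTrace],
                       config: AnalysisConfig | None = None) -> DominanceResult:
    """Label the dominant vessel: the one where fluorescence arrives first.

    If both arrivals fall within one frame interval of each other, the tie
    is broken by the higher mean intensity over the first 100 s after the
    earlier arrival (the dominant vessel nearly always runs brighter).  If
    only one vessel ever shows fluorescence, it is dominant.
    """
    labels = list(arrivals)
    if len(labels) != 2:
        raise ValueError("classify_dominance expects exactly two vessels")
    detected = [lbl for lbl in labels if arrivals[lbl].detected]
    if not detected:
        raise ValueError("neither vessel shows a detectable arrival")
    if len(detected) == 1:
        return DominanceResult(detected[0], flags=["single_vessel_detected"])

    t0, t1 = (arrivals[lbl].arrival_time_s for lbl in labels)
    frame_dt = min(traces[lbl].dt_s for lbl in labels)
    if abs(t0 - t1) >= frame_dt:
        return DominanceResult(labels[0] if t0 < t1 else labels[1])

    # tie-break on intensity over the first 100 s post-arrival
    start = min(t0, t1)
    means = {}
    for lbl in labels:
        sel = traces[lbl].slice(start, start + 100.0)
        means[lbl] = float(traces[lbl].values[sel].mean()) if sel.any() else -math.inf
    if means[labels[0]] == means[labels[1]]:
        return DominanceResult(labels[0], tie_break_used=True,
                               flags=["tie_unresolved_roi_order"])
    winner = max(labels, key=lambda l: means[l])
    return DominanceResult(winner, tie_break_used=True, flags=["tie_break_intensity"])


def analyze_session(stack: FrameStack, rois: Sequence[Roi],
                    config: AnalysisConfig | None = None,
                    week0_result: SessionResult | None = None,
                    animal_id: str = "animal", week: int = 0,
                    group: str = "treatment") -> SessionResult:
    """End-to-end quantification of one imaging session.

    Composes extraction → arrival → segments → detrend → packet detection →
    frequency/velocity for both vessel ROIs, then dominance classification.
    For follow-up sessions (week > 0) with a stored week-0 result, dominance
    labels are copied rather than recomputed, regardless of this session's
    transport times.  Stage failures degrade to NaN metrics with flags; the
    session never silently reports zeros.
    """
    cfg = config or AnalysisConfig()
    validate_session_rois(rois)
    vessel_rois = [r for r in rois if r.purpose == "vessel"][:2]
    background = next(r for r in rois if r.purpose == "background")

    traces: dict[str, IntensityTrace] = {}
    arrivals: dict[str, ArrivalResult] = {}
    metrics: dict[str, VesselMetrics] = {}
    session_flags: list[str] = []

    for roi in vessel_rois:
        tr = extract_trace(stack, roi, background)
        traces[roi.label] = tr
        arrivals[roi.label] = detect_arrival(tr, cfg)
        metrics[roi.label] = _vessel_metrics(stack, roi, background, tr,
                                             arrivals[roi.label], cfg)

    # dominance
    if week > 0 and week0_result is not None:
        if week0_result.dominant_label not in metrics:
            raise ValueError("week-0 dominant label does not match this session's ROIs")
        dominant = week0_result.dominant_label
        source = "week0_fixed"
    else:
        try:
            dom = classify_dominance(arrivals, traces, cfg)
            dominant = dom.label
            session_flags.extend(dom.flags)
        except ValueError:
            dominant = vessel_rois[0].label
            session_flags.append("no_arrival_detected")
        source = "week0_fixed" if week > 0 else "this_session"

    return SessionResult(
        animal_id=animal_id, week=week, group=group,
        metrics=metrics, dominant_label=dominant,
        dominance_source=source, flags=session_flags,
    )


def _vessel_metrics(stack: FrameStack, roi: Roi, background: Roi,
                    trace: IntensityTrace, arrival: ArrivalResult,
                    cfg: AnalysisConfig) -> VesselMetrics:
    m = VesselMetrics()
    if not arrival.detected:
        m.flags.append("arrival_not_detected")
        return m
    m.transport_time_s = transport_time(arrival)
    try:
        seg_arrival, seg_steady = define_segments(arrival, float(stack.times_s[-1]), cfg)
    except ValueError as exc:
        m.flags.append(f"segments_unavailable:{exc}")
        return m
    m.flags.extend(f"{s.name}:{f}" for s in (seg_arrival, seg_steady) for f in s.flags)

    subs = subdivide_vessel_roi(roi, cfg.n_subrois)
    sub_traces = [extract_trace(stack, s, background) for s in subs]
    positions = sub_roi_axial_midpoints_mm(subs, stack.pixel_size_mm)
    det_subs = [detrend(tr, config=cfg) for tr in sub_traces]

    # count packets at the central cross-section: a packet's pulse there is
    # narrow regardless of how long it takes to transit the whole window,
    # so slow vessels do not merge neighbouring packets
    det_mid = det_subs[len(det_subs) // 2]
    if "beyond_recording" not in seg_steady.flags:
        m.freq_steady = packet_frequency(detect_packets(det_mid, seg_steady, cfg), seg_steady)
    m.freq_arrival = packet_frequency(detect_packets(det_mid, seg_arrival, cfg), seg_arrival)
    for seg, attr in ((seg_arrival, "vel_arrival"), (seg_steady, "vel_steady")):
        if seg.name == "steady_state" and "beyond_recording" in seg.flags:
            continue
        est = packet_velocity(det_subs, seg, cfg, positions_mm=positions,
                              predetrended=True)
        setattr(m, attr, est.mm_s)
        if est.n_discarded:
            m.flags.append(f"{seg.name}:velocity_discarded={est.n_discarded}")
        if math.isnan(est.mm_s):
            m.flags.append(f"{seg.name}:velocity_missing")
    return m
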