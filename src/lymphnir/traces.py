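"""Per-ROI intensity traces and signal-to-noise computation.

The intensity trace — mean ROI intensity versus time — is the unit on which
all packet analysis operates.  Background statistics come from the
background ROI pooled over the first 10 s of recording, i.e. before tracer
can reach a window placed 10 cm downstream of the injection site.

SNR convention
--------------
``snr_db`` treats the mean signal excess over background as an *amplitude*
relative to the background standard deviation:

    SNR = 20 * log10((mean - background_mean) / background_sd)

A ``10 * log10`` power mode is available via ``mode="power"`` for
comparison with instruments that report power dB.  A non-positive excess
returns ``-inf`` ("not visible").
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .io import FrameStack, Roi

__all__ = ["IntensityTrace", "extract_trace", "snr_db", "subdivide_vessel_roi",
           "sub_roi_axial_midpoints_mm", "BACKGROUND_WINDOW_S"]

BACKGROUND_WINDOW_S = 10.0


@dataclass
class IntensityTrace:
    """Mean ROI intensity versus time with background statistics."""

    roi_label: str
    times_s: np.ndarray
    values: np.ndarray
    background_mean: float
    background_sd: float
    axial_mm: float | None = None  # axial midpoint of the source ROI, if any

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_s.shape != self.values.shape:
            raise ValueError("times_s and values must have equal length")
        if self.times_s.size and np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.background_sd < 0:
            raise ValueError("background_sd must be >= 0")

    @property
    def dt_s(self) -> float:
        return float(np.median(np.diff(self.times_s)))

    def slice(self, start_s: float, end_s: float) -> np.ndarray:
        """Index mask for samples with ``start_s <= t <= end_s``."""
        return (self.times_s >= start_s) & (self.times_s <= end_s)

    def shifted(self, dt: float) -> "IntensityTrace":
        return replace(self, times_s=self.times_s + dt)


def extract_trace(stack: FrameStack, roi: Roi, background_roi: Roi) -> IntensityTrace:
    """Reduce a video stack to the mean-intensity trace of one ROI.

    ``values[i]`` is the mean over the ROI pixels in frame ``i``.  Background
    mean/sd are computed from the *pixel pool* of the background ROI over the
    first 10 s of frames (or all frames for shorter recordings), so
    ``background_sd`` estimates per-pixel noise.
    """
    t, h, w = stack.shape
    mask = roi.mask(h, w)
    if not mask.any():
        raise ValueError(f"ROI {roi.label!r} selects no pixels")
    bg_mask = background_roi.mask(h, w)
    if not bg_mask.any():
        raise ValueError(f"background ROI {background_roi.label!r} selects no pixels")
    if np.any(mask & bg_mask):
        raise ValueError("background ROI must be disjoint from the signal ROI")

    values = stack.frames[:, mask].mean(axis=1)
    n_bg = max(1, min(t, int(round(BACKGROUND_WINDOW_S / stack.frame_interval_s))))
    pool = stack.frames[:n_bg][:, bg_mask].astype(float)
    return IntensityTrace(
        roi_label=roi.label,
        times_s=stack.times_s,
        values=values,
        background_mean=float(pool.mean()),
        background_sd=float(pool.std(ddof=1)) if pool.size > 1 else 0.0,
        axial_mm=roi.axial_midpoint_mm(stack.pixel_size_mm) if roi.purpose == "vessel" else None,
    )


def snr_db(trace: IntensityTrace, window: tuple[float, float] | None = None,
           mode: str = "amplitude") -> float:
    """Signal-to-noise ratio of a trace window in dB.

    Parameters
    ----------
    window
        ``(start_s, end_s)`` inclusive; ``None`` uses the whole trace.
    mode
        ``"amplitude"`` (20·log10, default) or ``"power"`` (10·log10).

    Returns ``-inf`` when the mean does not exceed background ("not
    visible").  Raises on zero background SD.
    """
    if trace.background_sd <= 0:
        raise ValueError("snr_db requires background_sd > 0")
    if mode not in ("amplitude", "power"):
        raise ValueError(f"unknown SNR mode {mode!r}")
    if window is None:
        vals = trace.values
    else:
        start_s, end_s = window
        sel = trace.slice(start_s, end_s)
        if not sel.any():
            raise ValueError("window lies outside the trace support")
        vals = trace.values[sel]
    excess = float(vals.mean()) - trace.background_mean
    if excess <= 0:
        return float("-inf")
    factor = 20.0 if mode == "amplitude" else 10.0
    return factor * float(np.log10(excess / trace.background_sd))


def subdivide_vessel_roi(roi: Roi, n: int) -> list[Roi]:
    """Split a vessel ROI into ``n`` contiguous equal-axial-length sub-ROIs.

    Sub-ROIs are ordered from injection-proximal to distal and carry axial
    origins so their midpoints (``Roi.axial_midpoint_mm``) are well defined.
    Together they partition the parent pixel mask exactly.
    """
    if roi.purpose != "vessel":
        raise ValueError("subdivide_vessel_roi expects a vessel ROI")
    if n < 2:
        raise ValueError("n must be >= 2")
    if roi.kind == "rect":
        if n > roi.width:
            raise ValueError(f"n={n} exceeds ROI axial pixel count {roi.width}")
        edges = np.round(np.linspace(0, roi.width, n + 1)).astype(int)
        return [
            Roi(
                label=f"{roi.label}/{k}",
                purpose="vessel",
                kind="rect",
                x=roi.x + int(edges[k]), y=roi.y,
                width=int(edges[k + 1] - edges[k]), height=roi.height,
                axial_origin_mm=roi.axial_origin_mm,
                axial_offset_px=roi.axial_offset_px + float(edges[k]),
            )
            for k in range(n)
        ]
    # polyline: split by cumulative arc length
    pts = np.asarray(roi.points, dtype=float)
    seg = np.hypot(*np.diff(pts, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if n > max(2, int(total)):
        raise ValueError(f"n={n} exceeds polyline axial pixel length {total:.0f}")
    targets = np.linspace(0, total, n + 1)
    subs = []
    for k in range(n):
        s0, s1 = targets[k], targets[k + 1]
        sub_pts = [_interp_along(pts, cum, s0)]
        inner = (cum > s0) & (cum < s1)
        sub_pts.extend(map(tuple, pts[inner]))
        sub_pts.append(_interp_along(pts, cum, s1))
        subs.append(Roi(
            label=f"{roi.label}/{k}",
            purpose="vessel",
            kind="polyline",
            points=sub_pts,
            width_px=roi.width_px,
            axial_origin_mm=roi.axial_origin_mm,
            axial_offset_px=roi.axial_offset_px + float(targets[k]),
        ))
    return subs


def sub_roi_axial_midpoints_mm(subs: Sequence[Roi], pixel_size_mm: float) -> np.ndarray:
    """Axial midpoints (mm from injection site) of subdivided vessel ROIs."""
    return np.asarray([sub.axial_midpoint_mm(pixel_size_mm) for sub in subs])


def _interp_along(pts: np.ndarray, cum: np.ndarray, s: float) -> tuple[float, float]:
    i = int(np.searchsorted(cum, s, side="right")) - 1
    i = min(max(i, 0), len(pts) - 2)
    span = cum[i + 1] - cum[i]
    f = 0.0 if span == 0 else (s - cum[i]) / span
    p = pts[i] + f * (pts[i + 1] - pts[i])
    return (float(p[0]), float(p[1]))
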