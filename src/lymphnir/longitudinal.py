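"""Longitudinal analyses: tracer retention, percent change, node morphometry.

The week 0/1/2/4 design tracks three things after an initial tracer
injection: how long the tracer stays visible at the injection site (SNR
above the 3 dB visibility limit, sampled every 2 days), how the vessel
function metrics change relative to the week-0 baseline, and whether the
draining lymph node enlarges (projected 2-D area from microscopy images).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure

from .config import AnalysisConfig
from .io import FrameStack, Roi
from .packets import SessionResult
from .traces import extract_trace, snr_db

__all__ = [
    "RetentionPoint", "NodeMeasurement",
    "retention_curve", "percent_change", "node_area", "compile_timecourse",
    "sessions_from_results", "METRIC_COLUMNS",
]


@dataclass
class RetentionPoint:
    """Injection-site SNR at one follow-up day."""

    day: int
    snr_db: float
    visible: bool  # snr_db > visibility limit (3 dB)


@dataclass
class NodeMeasurement:
    animal_id: str
    week: int
    group: str
    area_mm2: float

    def __post_init__(self) -> None:
        if not self.area_mm2 > 0:
            raise ValueError("node area must be positive")


def retention_curve(stacks: Sequence[tuple[int, FrameStack]],
                    injection_roi: Roi, background_roi: Roi,
                    config: AnalysisConfig | None = None,
                    ) -> tuple[list[RetentionPoint], int | None]:
    """Per-day injection-site SNR and the last day the tracer is visible.

    Returns ``(points, last_visible_day)``; ``last_visible_day`` is ``None``
    when the signal never exceeds the visibility limit.
    """
    cfg = config or AnalysisConfig()
    if len(stacks) < 2:
        raise ValueError("retention needs at least two time points")
    days = [d for d, _ in stacks]
    if 0 not in days:
        raise ValueError("retention series must include a day-0 reference")
    points = []
    for day, stack in sorted(stacks, key=lambda p: p[0]):
        trace = extract_trace(stack, injection_roi, background_roi)
        s = snr_db(trace, mode=cfg.snr_mode)
        points.append(RetentionPoint(day=day, snr_db=s,
                                     visible=s > cfg.snr_visibility_db))
    visible_days = [p.day for p in points if p.visible]
    return points, (max(visible_days) if visible_days else None)


def percent_change(baseline: float, followup: float) -> float:
    """``100 * (followup - baseline) / baseline``; zero baseline is an error."""
    if baseline == 0:
        raise ValueError("percent change undefined for zero baseline")
    return 100.0 * (followup - baseline) / baseline


def node_area(image: np.ndarray, pixel_size_mm: float) -> float:
    """Projected 2-D node area in mm².

    Binary masks are counted exactly.  Grayscale images are segmented by
    Otsu threshold, keeping the largest connected component with holes
    filled — a standard reconstruction of "projected two-dimensional area".
    """
    image = np.asarray(image)
    if not pixel_size_mm > 0:
        raise ValueError("pixel_size_mm must be positive")
    if image.dtype == bool:
        n = int(image.sum())
        if n == 0:
            raise ValueError("empty foreground")
        return n * pixel_size_mm**2
    thr = filters.threshold_otsu(image)
    fg = image > thr
    if not fg.any():
        raise ValueError("empty foreground after thresholding")
    labels = measure.label(fg)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = ndimage.binary_fill_holes(labels == largest)
    return float(mask.sum()) * pixel_size_mm**2


METRIC_COLUMNS = ["animal_id", "week", "group", "vessel", "metric", "segment",
                  "value", "baseline_value", "percent_change"]

# (metric name, VesselMetrics field, segment label)
_METRIC_FIELDS = [
    ("transport_time", "transport_time_s", "overall"),
    ("packet_frequency", "freq_arrival", "arrival"),
    ("packet_frequency", "freq_steady", "steady_state"),
    ("packet_velocity", "vel_arrival", "arrival"),
    ("packet_velocity", "vel_steady", "steady_state"),
]


def compile_timecourse(sessions: Sequence[SessionResult],
                       nodes: Sequence[NodeMeasurement] = (),
                       ) -> pd.DataFrame:
    """Tidy table for the week 0/1/2/4 comparisons.

    One row per animal·week·vessel·metric·segment, with each follow-up row
    linked to the same animal/vessel/metric week-0 baseline and its percent
    change.  Vessels are identified by their dominance role (fixed at week
    0).  Missing metrics propagate as NaN and are excluded from the paired
    tests downstream.
    """
    rows = []
    for sr in sessions:
        for role, m in sr.by_role().items():
            for metric, fieldname, segment in _METRIC_FIELDS:
                rows.append({
                    "animal_id": sr.animal_id, "week": sr.week, "group": sr.group,
                    "vessel": role, "metric": metric, "segment": segment,
                    "value": getattr(m, fieldname),
                })
    for nm in nodes:
        rows.append({
            "animal_id": nm.animal_id, "week": nm.week, "group": nm.group,
            "vessel": "node", "metric": "node_area", "segment": "overall",
            "value": nm.area_mm2,
        })
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=METRIC_COLUMNS)

    base = (df[df["week"] == 0]
            .rename(columns={"value": "baseline_value"})
            [["animal_id", "vessel", "metric", "segment", "baseline_value"]])
    out = df.merge(base, on=["animal_id", "vessel", "metric", "segment"], how="left")

    # a follow-up without *any* week-0 row for that animal is a design error
    followups = out[out["week"] > 0]
    have_week0 = set(df.loc[df["week"] == 0, "animal_id"])
    orphans = set(followups["animal_id"]) - have_week0
    if orphans:
        raise ValueError(f"follow-up without week-0 baseline for animals {sorted(orphans)}")

    with np.errstate(divide="ignore", invalid="ignore"):
        pc = 100.0 * (out["value"] - out["baseline_value"]) / out["baseline_value"]
    out["percent_change"] = pc.where(out["baseline_value"] != 0, np.nan)
    out.loc[out["week"] == 0, "percent_change"] = 0.0
    return out[METRIC_COLUMNS]


def sessions_from_results(df: pd.DataFrame) -> list[SessionResult]:
    """Rebuild :class:`SessionResult` objects from a written results table
    (the :func:`lymphnir.io.write_results` schema), so stored per-session
    CSVs can be compiled into the timecourse table."""
    from .packets import VesselMetrics  # local import to avoid cycle at import time

    sessions = []
    for (animal, week, group), grp in df.groupby(["animal_id", "week", "group"], sort=True):
        metrics: dict[str, VesselMetrics] = {}
        dominant = None
        source = "this_session"
        for _, row in grp.iterrows():
            metrics[row["vessel_label"]] = VesselMetrics(
                transport_time_s=row["transport_time_s"],
                freq_arrival=row["freq_arrival_per_min"],
                freq_steady=row["freq_steady_per_min"],
                vel_arrival=row["vel_arrival_mm_s"],
                vel_steady=row["vel_steady_mm_s"],
            )
            if row["vessel_role"] == "dominant":
                dominant = row["vessel_label"]
                source = row["dominance_source"]
        if dominant is None:
            raise ValueError(f"no dominant vessel recorded for {animal} week {week}")
        sessions.append(SessionResult(
            animal_id=str(animal), week=int(week), group=str(group),
            metrics=metrics, dominant_label=dominant, dominance_source=source,
        ))
    return sessions
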