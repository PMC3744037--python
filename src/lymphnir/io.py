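"""Reading and writing of imaging data, ROI definitions and result tables.

All file formats used by the package are pinned down here:

* video stacks: multi-page grayscale TIFF plus a YAML sidecar carrying the
  temporal/spatial calibration (``frame_interval_s``, ``pixel_size_mm``,
  ``t0_s``),
* regions of interest: a small JSON schema (rectangles or widened
  polylines, 0-based half-open pixel coordinates),
* per-session metric tables: flat CSV, one row per vessel per session.

Times are seconds since tracer injection; ``t0_s`` shifts sessions whose
recording started late.  Axial distance is measured in millimetres from the
injection site, with the imaging window conventionally starting 100 mm
(10 cm) downstream.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "FrameStack",
    "Roi",
    "MetadataError",
    "RoiValidationError",
    "read_stack",
    "write_stack",
    "read_rois",
    "write_rois",
    "validate_session_rois",
    "write_results",
    "read_results",
    "config_hash",
    "RESULT_COLUMNS",
]

DEFAULT_AXIAL_ORIGIN_MM = 100.0  # imaging window 10 cm downstream of injection


class MetadataError(ValueError):
    """A stack is missing or carries inconsistent calibration metadata."""


class RoiValidationError(ValueError):
    """An ROI set violates the documented schema or geometry rules."""


@dataclass
class FrameStack:
    """Time-ordered 2-D intensity frames with calibration.

    Attributes
    ----------
    frames
        ``(T, H, W)`` non-negative intensity array.
    frame_interval_s
        Seconds between consecutive frames (camera exposure cadence).
    pixel_size_mm
        Physical size of one pixel in mm.
    t0_s
        Recording start relative to injection (seconds, default 0).
    """

    frames: np.ndarray
    frame_interval_s: float
    pixel_size_mm: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (T, H, W) array with T >= 1")
        if not self.frame_interval_s > 0:
            raise ValueError("frame_interval_s must be positive")
        if not self.pixel_size_mm > 0:
            raise ValueError("pixel_size_mm must be positive")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.frames.shape)  # type: ignore[return-value]

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s

    @property
    def times_s(self) -> np.ndarray:
        """Frame timestamps, seconds since injection (strictly increasing)."""
        return self.t0_s + np.arange(self.n_frames) * self.frame_interval_s


@dataclass
class Roi:
    """Region of interest in pixel coordinates (0-based, half-open).

    Two geometries are supported: an axis-aligned rectangle
    (``kind="rect"``, fields ``x, y, width, height``) whose axial direction
    runs along +x (from injection toward the tail base), and a centerline
    polyline with a width (``kind="polyline"``, fields ``points``,
    ``width_px``) ordered from injection-proximal to distal.
    """

    label: str
    purpose: str  # vessel | background | injection_site | node
    kind: str = "rect"
    x: int = 0
    y: int = 0
    width: int = 0
    height: int = 0
    points: list[tuple[float, float]] = field(default_factory=list)
    width_px: float = 1.0
    axial_origin_mm: float = DEFAULT_AXIAL_ORIGIN_MM
    axial_offset_px: float = 0.0  # set on sub-ROIs carved from a parent vessel ROI

    _PURPOSES = ("vessel", "background", "injection_site", "node")

    def __post_init__(self) -> None:
        if self.purpose not in self._PURPOSES:
            raise RoiValidationError(
                f"unknown ROI purpose {self.purpose!r}; expected one of {self._PURPOSES}"
            )
        if self.kind == "rect":
            if self.width < 1 or self.height < 1:
                raise RoiValidationError(f"rect ROI {self.label!r} must have positive size")
        elif self.kind == "polyline":
            if len(self.points) < 2:
                raise RoiValidationError(f"polyline ROI {self.label!r} needs >= 2 points")
            if not self.width_px > 0:
                raise RoiValidationError(f"polyline ROI {self.label!r} needs positive width")
        else:
            raise RoiValidationError(f"unknown ROI kind {self.kind!r}")

    # -- geometry -----------------------------------------------------------

    def axial_length_px(self) -> float:
        if self.kind == "rect":
            return float(self.width)
        pts = np.asarray(self.points, dtype=float)
        return float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))

    def axial_length_mm(self, pixel_size_mm: float) -> float:
        """Axial extent in mm (rect width, or polyline arc length)."""
        return self.axial_length_px() * pixel_size_mm

    def axial_midpoint_mm(self, pixel_size_mm: float) -> float:
        """Axial midpoint in mm from the injection site."""
        return self.axial_origin_mm + (
            self.axial_offset_px + 0.5 * self.axial_length_px()
        ) * pixel_size_mm

    def bounds(self) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max); half-open for rects."""
        if self.kind == "rect":
            return (self.x, self.y, self.x + self.width, self.y + self.height)
        pts = np.asarray(self.points, dtype=float)
        half = self.width_px / 2.0
        return (
            float(pts[:, 0].min() - half),
            float(pts[:, 1].min() - half),
            float(pts[:, 0].max() + half + 1),
            float(pts[:, 1].max() + half + 1),
        )

    def mask(self, height: int, width: int) -> np.ndarray:
        """Boolean pixel mask of shape ``(height, width)``."""
        if self.kind == "rect":
            m = np.zeros((height, width), dtype=bool)
            m[self.y : self.y + self.height, self.x : self.x + self.width] = True
            return m
        # polyline: pixels within width/2 of any centerline segment
        yy, xx = np.mgrid[0:height, 0:width]
        pix = np.stack([xx.ravel(), yy.ravel()], axis=1).astype(float)
        dmin = np.full(pix.shape[0], np.inf)
        pts = np.asarray(self.points, dtype=float)
        for a, b in zip(pts[:-1], pts[1:]):
            ab = b - a
            denom = float(ab @ ab)
            t = np.clip((pix - a) @ ab / denom, 0.0, 1.0) if denom > 0 else 0.0
            proj = a + np.outer(t, ab) if denom > 0 else np.broadcast_to(a, pix.shape)
            d = np.hypot(*(pix - proj).T)
            dmin = np.minimum(dmin, d)
        return (dmin <= self.width_px / 2.0).reshape(height, width)

    def in_bounds(self, height: int, width: int) -> bool:
        x0, y0, x1, y1 = self.bounds()
        return x0 >= 0 and y0 >= 0 and x1 <= width and y1 <= height

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {
            "label": self.label,
            "purpose": self.purpose,
            "shape": self.kind,
            "axial_origin_mm": self.axial_origin_mm,
        }
        if self.kind == "rect":
            d.update(x=self.x, y=self.y, width=self.width, height=self.height)
        else:
            d.update(points=[list(p) for p in self.points], width_px=self.width_px)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Roi":
        kind = d.get("shape", d.get("kind", "rect"))
        common = dict(
            label=d["label"],
            purpose=d["purpose"],
            kind=kind,
            axial_origin_mm=float(d.get("axial_origin_mm", DEFAULT_AXIAL_ORIGIN_MM)),
        )
        if kind == "rect":
            return cls(
                x=int(d["x"]), y=int(d["y"]),
                width=int(d["width"]), height=int(d["height"]),
                **common,
            )
        return cls(
            points=[tuple(map(float, p)) for p in d["points"]],
            width_px=float(d.get("width_px", 1.0)),
            **common,
        )


# ---------------------------------------------------------------------------
# stacks


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".yaml")


def write_stack(stack: FrameStack, path: str | Path) -> Path:
    """Write a multi-page TIFF plus YAML calibration sidecar.

    The pixel array is stored in its native dtype so write→read round-trips
    are bit-exact.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.frames, photometric="minisblack")
    meta = {
        "frame_interval_s": float(stack.frame_interval_s),
        "pixel_size_mm": float(stack.pixel_size_mm),
        "t0_s": float(stack.t0_s),
    }
    _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def read_stack(path: str | Path) -> FrameStack:
    """Read a calibrated FrameStack (TIFF + YAML sidecar).

    Missing calibration is an error, never a silent default.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MetadataError(f"missing metadata sidecar {sidecar}")
    meta = yaml.safe_load(sidecar.read_text())
    if not isinstance(meta, dict) or "frame_interval_s" not in meta:
        raise MetadataError(f"sidecar {sidecar} lacks frame_interval_s")
    if "pixel_size_mm" not in meta:
        raise MetadataError(f"sidecar {sidecar} lacks pixel_size_mm")
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise MetadataError(f"{path}: expected a T x H x W grayscale stack")
    return FrameStack(
        frames=frames,
        frame_interval_s=float(meta["frame_interval_s"]),
        pixel_size_mm=float(meta["pixel_size_mm"]),
        t0_s=float(meta.get("t0_s", 0.0)),
    )


# ---------------------------------------------------------------------------
# ROIs


def _check_overlaps(rois: Sequence[Roi], frame_shape: tuple[int, int] | None) -> None:
    checked = [r for r in rois if r.purpose in ("vessel", "background")]
    if len(checked) < 2:
        return
    if frame_shape is None:
        x1 = max(int(math.ceil(r.bounds()[2])) for r in checked)
        y1 = max(int(math.ceil(r.bounds()[3])) for r in checked)
        frame_shape = (y1, x1)
    h, w = frame_shape
    masks = [r.mask(h, w) for r in checked]
    for i in range(len(checked)):
        for j in range(i + 1, len(checked)):
            if np.any(masks[i] & masks[j]):
                raise RoiValidationError(
                    f"ROIs {checked[i].label!r} and {checked[j].label!r} overlap"
                )


def read_rois(path: str | Path, frame_shape: tuple[int, int] | None = None) -> list[Roi]:
    """Read and validate an ROI set from the documented JSON schema.

    If ``frame_shape`` ``(H, W)`` is given, geometry is checked against it.
    Vessel/background overlap is always an error.
    """
    doc = json.loads(Path(path).read_text())
    items = doc["rois"] if isinstance(doc, dict) else doc
    rois = [Roi.from_dict(d) for d in items]
    if frame_shape is not None:
        h, w = frame_shape
        for r in rois:
            if not r.in_bounds(h, w):
                raise RoiValidationError(f"ROI {r.label!r} exceeds frame bounds {h}x{w}")
    _check_overlaps(rois, frame_shape)
    return rois


def write_rois(rois: Sequence[Roi], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps({"rois": [r.to_dict() for r in rois]}, indent=2))
    return path


def validate_session_rois(rois: Sequence[Roi]) -> None:
    """A function-imaging session needs >= 2 vessel ROIs and exactly 1 background."""
    vessels = [r for r in rois if r.purpose == "vessel"]
    backgrounds = [r for r in rois if r.purpose == "background"]
    if len(vessels) < 2:
        raise RoiValidationError(f"need >= 2 vessel ROIs, got {len(vessels)}")
    if len(backgrounds) != 1:
        raise RoiValidationError(f"need exactly 1 background ROI, got {len(backgrounds)}")


# ---------------------------------------------------------------------------
# result tables

RESULT_COLUMNS = [
    "animal_id",
    "week",
    "group",
    "vessel_label",
    "vessel_role",
    "dominance_source",
    "transport_time_s",
    "freq_arrival_per_min",
    "freq_steady_per_min",
    "vel_arrival_mm_s",
    "vel_steady_mm_s",
    "flags",
]


def config_hash(config_mapping: dict) -> str:
    """Stable sha256 of a configuration mapping (canonical YAML dump)."""
    dump = yaml.safe_dump(config_mapping, sort_keys=True)
    return hashlib.sha256(dump.encode()).hexdigest()[:16]


def write_results(session_results: Sequence, path: str | Path,
                  config_hash_hex: str | None = None) -> Path:
    """Write a flat CSV, one row per vessel per session.

    Missing metrics are empty cells (explicit nulls), never zeros.  The
    configuration hash, when given, is embedded as a ``#`` comment header so
    result provenance survives copying the file around.
    """
    rows = []
    for sr in session_results:
        rows.extend(sr.to_rows())
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        if config_hash_hex:
            fh.write(f"# config_sha256={config_hash_hex}\n")
        df.to_csv(fh, index=False, lineterminator="\n")
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
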