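"""Carapace size pipeline: keypoints -> pixel segments -> millimetres.

Width is the segment joining the left and right carapace margin points,
length the segment joining the front and behind points.  The two eyes,
which always sit on the anterior half of the shell, disambiguate a 180-degree
labeling error before measurement.

Pixel lengths convert to physical units through a calibration plate of known
side length (mm per pixel = plate side / mean pixel side length), optionally
refined by the linear regression

    d_real = a * d_pixel + b,

whose intercept absorbs the systematic offset between the projected shell
outline and caliper-measured size (the crab's thickness raises the shell
toward the camera).  The regression, when fitted, takes precedence over the
pure plate scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats
from shapely.geometry import Polygon

from .core import (
    AmbiguousOrientationError,
    CrabKeypointSet,
    DegenerateFitError,
    ImplausibleMeasurementError,
    InvalidInputError,
    InvalidPlateError,
    Keypoint,
    MissingKeypointError,
)

__all__ = [
    "CalibrationModel",
    "CarapaceMeasurement",
    "ErrorReport",
    "carapace_segments",
    "orientation_check",
    "scale_from_plate",
    "fit_calibration",
    "apply_calibration",
    "measure_carapace",
    "error_report",
]

_SIDE_NAMES = ("left_side", "right_side", "front_side", "behind_side")


@dataclass(frozen=True)
class CalibrationModel:
    """Pixel-to-millimetre conversion.

    With ``n_fit == 0`` the model is the pure plate scale (slope equals
    ``mm_per_pixel``, intercept 0); with ``n_fit >= 2`` the slope/intercept
    come from an ordinary least-squares fit of paired (pixel, mm) samples,
    and standard errors of the coefficients are retained.
    """

    mm_per_pixel: float
    a: float
    b: float = 0.0
    n_fit: int = 0
    a_stderr: float | None = None
    b_stderr: float | None = None

    def __post_init__(self) -> None:
        if not (self.mm_per_pixel > 0):
            raise InvalidInputError(f"mm_per_pixel must be > 0, got {self.mm_per_pixel}")

    @property
    def fitted(self) -> bool:
        return self.n_fit >= 2

    @property
    def mode(self) -> str:
        return "regression" if self.fitted else "plate_scale"

    @classmethod
    def from_scale(cls, mm_per_pixel: float) -> "CalibrationModel":
        return cls(mm_per_pixel=mm_per_pixel, a=mm_per_pixel, b=0.0, n_fit=0)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CalibrationModel":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class CarapaceMeasurement:
    """One crab's width/length in pixels and millimetres."""

    width_px: float
    length_px: float
    width_mm: float
    length_mm: float
    calibration_mode: str = "plate_scale"

    def __post_init__(self) -> None:
        for name in ("width_px", "length_px", "width_mm", "length_mm"):
            if not (getattr(self, name) > 0):
                raise ImplausibleMeasurementError(
                    f"{name} must be > 0, got {getattr(self, name)}"
                )


@dataclass(frozen=True)
class ErrorReport:
    """Signed per-sample relative errors (%) and their absolute summary."""

    per_sample_rel_error: tuple[float, ...]
    max_abs_rel_error: float
    mean_abs_rel_error: float


def _point(kps: CrabKeypointSet, name: str) -> np.ndarray:
    kp = kps[name]
    if not kp.visible:
        raise MissingKeypointError(f"required keypoint {name!r} is not visible")
    return np.array([kp.x, kp.y], dtype=float)


def carapace_segments(kps: CrabKeypointSet) -> tuple[float, float]:
    """(width_px, length_px): distances left-right and front-behind.

    All four side keypoints must be visible; a missing one raises
    :class:`MissingKeypointError` naming it.
    """
    left, right = _point(kps, "left_side"), _point(kps, "right_side")
    front, behind = _point(kps, "front_side"), _point(kps, "behind_side")
    width = float(np.linalg.norm(right - left))
    length = float(np.linalg.norm(front - behind))
    return width, length


def orientation_check(kps: CrabKeypointSet) -> CrabKeypointSet:
    """Ensure the eyes lie on the front half of the left-right axis.

    The eye midpoint must fall on the same side of the left-right axis as
    the front keypoint.  If it does not, the labeling is rotated 180 degrees
    (front/behind swapped AND left/right swapped); the result always
    satisfies the eye-side condition, and the operation is idempotent.
    """
    left, right = _point(kps, "left_side"), _point(kps, "right_side")
    front = _point(kps, "front_side")
    _point(kps, "behind_side")
    eye_mid = 0.5 * (_point(kps, "left_eye") + _point(kps, "right_eye"))
    axis = right - left

    def side_of(p: np.ndarray) -> float:
        # z-component of axis x (p - left); sign convention irrelevant, only
        # agreement between eyes and front matters
        return float(axis[0] * (p[1] - left[1]) - axis[1] * (p[0] - left[0]))

    side_eyes = side_of(eye_mid)
    side_front = side_of(front)
    if side_eyes == 0.0:
        raise AmbiguousOrientationError("eye midpoint lies exactly on the left-right axis")
    if side_front == 0.0 or (side_eyes > 0) == (side_front > 0):
        return kps
    def relabel(kp: Keypoint, name: str) -> Keypoint:
        return Keypoint(name, kp.x, kp.y, kp.visibility, kp.confidence)
    return kps.with_replaced(
        front_side=relabel(kps["behind_side"], "front_side"),
        behind_side=relabel(kps["front_side"], "behind_side"),
        left_side=relabel(kps["right_side"], "left_side"),
        right_side=relabel(kps["left_side"], "right_side"),
    )


def scale_from_plate(
    plate_corners_px: Sequence[tuple[float, float]], plate_side_mm: float
) -> float:
    """mm per pixel from the four plate corners and the known side length.

    The estimate divides the physical side by the mean of the four pixel
    side lengths, absorbing mild perspective skew.  Corners must be given
    in traversal order and form a convex, non-self-intersecting quad.
    """
    if len(plate_corners_px) != 4:
        raise InvalidPlateError(f"expected 4 corners, got {len(plate_corners_px)}")
    if not (plate_side_mm > 0):
        raise InvalidInputError(f"plate_side_mm must be > 0, got {plate_side_mm}")
    poly = Polygon(plate_corners_px)
    if not poly.is_valid or poly.area <= 0:
        raise InvalidPlateError("plate corners self-intersect or are degenerate")
    if abs(poly.convex_hull.area - poly.area) > 1e-9 * poly.convex_hull.area:
        raise InvalidPlateError("plate corners do not form a convex quadrilateral")
    pts = np.asarray(plate_corners_px, dtype=float)
    sides = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
    return float(plate_side_mm / sides.mean())


def fit_calibration(
    samples: Sequence[tuple[float, float]],
    mm_per_pixel: float | None = None,
) -> CalibrationModel:
    """Ordinary least squares fit of d_real = a * d_pixel + b.

    ``samples`` holds (pixel distance, measured physical size in mm) pairs.
    ``mm_per_pixel`` records the plate scale alongside the regression; when
    omitted, the fitted slope serves as the equivalent scale.
    """
    if len(samples) < 2:
        raise DegenerateFitError("at least 2 samples are required")
    x = np.asarray([s[0] for s in samples], dtype=float)
    y = np.asarray([s[1] for s in samples], dtype=float)
    if np.allclose(x, x[0]):
        raise DegenerateFitError("all pixel distances identical; slope not identifiable")
    res = stats.linregress(x, y)
    scale = mm_per_pixel if mm_per_pixel is not None else float(res.slope)
    return CalibrationModel(
        mm_per_pixel=scale,
        a=float(res.slope),
        b=float(res.intercept),
        n_fit=len(samples),
        a_stderr=float(res.stderr) if len(samples) > 2 else None,
        b_stderr=float(res.intercept_stderr) if len(samples) > 2 else None,
    )


def apply_calibration(d_px: float, cal: CalibrationModel) -> float:
    """Convert a pixel distance to millimetres.

    Uses the fitted regression when present, otherwise the pure plate
    scale.  A non-positive result raises
    :class:`ImplausibleMeasurementError`.
    """
    if not (d_px > 0):
        raise InvalidInputError(f"d_px must be > 0, got {d_px}")
    mm = cal.a * d_px + cal.b if cal.fitted else cal.mm_per_pixel * d_px
    if mm <= 0:
        raise ImplausibleMeasurementError(
            f"calibrated size {mm} mm is non-positive for d_px={d_px}"
        )
    return mm


def measure_carapace(
    kps: CrabKeypointSet,
    calibration: CalibrationModel,
    length_calibration: CalibrationModel | None = None,
    check_orientation: bool = True,
) -> CarapaceMeasurement:
    """Full per-crab pipeline: orientation check, segments, calibration.

    A separate ``length_calibration`` may be supplied when width and length
    were regressed independently; otherwise ``calibration`` serves both.
    """
    if check_orientation:
        kps = orientation_check(kps)
    width_px, length_px = carapace_segments(kps)
    cal_l = length_calibration if length_calibration is not None else calibration
    return CarapaceMeasurement(
        width_px=width_px,
        length_px=length_px,
        width_mm=apply_calibration(width_px, calibration),
        length_mm=apply_calibration(length_px, cal_l),
        calibration_mode=calibration.mode,
    )


def error_report(estimates_mm: Sequence[float], truths_mm: Sequence[float]) -> ErrorReport:
    """Relative measurement errors against ground truth.

    Per sample: (estimate - truth) / truth * 100; the report carries the
    signed values plus the max and mean of their absolute values.
    """
    if len(estimates_mm) != len(truths_mm) or not estimates_mm:
        raise InvalidInputError("estimates and truths must have equal nonzero length")
    if any(t <= 0 for t in truths_mm):
        raise InvalidInputError("all truth values must be > 0")
    rel = [
        100.0 * (e - t) / t for e, t in zip(estimates_mm, truths_mm)
    ]
    abs_rel = [abs(r) for r in rel]
    return ErrorReport(
        per_sample_rel_error=tuple(rel),
        max_abs_rel_error=max(abs_rel),
        mean_abs_rel_error=float(np.mean(abs_rel)),
    )
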