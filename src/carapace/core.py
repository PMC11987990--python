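"""Domain types for carapace keypoint detection and measurement.

Coordinate convention is the image convention throughout: origin at the
top-left corner, x increasing rightward, y increasing downward, continuous
(sub-pixel) coordinates.  A pure reporting transform to a bottom-left
Cartesian frame is provided by :func:`to_cartesian` for display output only;
all geometry (IoU, distances) is frame-invariant.

Boxes are stored in corner form ``(x_min, y_min, x_max, y_max)``;
center form ``(cx, cy, w, h)`` exists only at format boundaries
(see :mod:`carapace.io_formats`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

__all__ = [
    "KEYPOINT_NAMES",
    "FLIP_PAIRS",
    "CarapaceError",
    "InvalidInputError",
    "UndefinedOKSError",
    "UndefinedMetricError",
    "MissingKeypointError",
    "AmbiguousOrientationError",
    "DegenerateFitError",
    "InvalidPlateError",
    "ImplausibleMeasurementError",
    "BoundingBox",
    "Keypoint",
    "CrabKeypointSet",
    "Annotation",
    "PredictionRecord",
    "LossWeights",
    "validate_annotation",
    "to_cartesian",
]

#: The fixed 6-point anatomical schema, in serialization order: the two eyes
#: and the four extreme points of the dorsal carapace margin.
KEYPOINT_NAMES: tuple[str, ...] = (
    "left_eye",
    "right_eye",
    "left_side",
    "right_side",
    "front_side",
    "behind_side",
)

#: Laterally paired labels, swapped under horizontal mirroring.
FLIP_PAIRS: tuple[tuple[str, str], ...] = (
    ("left_eye", "right_eye"),
    ("left_side", "right_side"),
)


class CarapaceError(Exception):
    """Base class for all errors raised by this package."""


class InvalidInputError(CarapaceError, ValueError):
    """An argument violates a documented precondition."""


class UndefinedOKSError(CarapaceError):
    """OKS requested for an instance with no visible target keypoints."""


class UndefinedMetricError(CarapaceError):
    """A metric's denominator is zero; the value is absent, never 0."""


class MissingKeypointError(CarapaceError):
    """A required keypoint is absent or invisible; carries its name."""


class AmbiguousOrientationError(CarapaceError):
    """The eye midpoint lies exactly on the left-right axis."""


class DegenerateFitError(CarapaceError):
    """Calibration regression has no unique solution."""


class InvalidPlateError(CarapaceError):
    """Plate corners do not form a convex, non-self-intersecting quad."""


class ImplausibleMeasurementError(CarapaceError):
    """A calibrated physical size came out non-positive."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in pixel coordinates, corner form.

    Degenerate boxes (non-positive width or height) are constructible so
    that validators can report them; geometric operations reject them.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    def is_valid(self) -> bool:
        """True iff the box has strictly positive width and height."""
        return (
            self.width > 0
            and self.height > 0
            and all(math.isfinite(v) for v in (self.x_min, self.y_min, self.x_max, self.y_max))
        )

    def translated(self, dx: float, dy: float) -> "BoundingBox":
        return BoundingBox(self.x_min + dx, self.y_min + dy, self.x_max + dx, self.y_max + dy)

    @classmethod
    def from_center(cls, cx: float, cy: float, w: float, h: float) -> "BoundingBox":
        return cls(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)


@dataclass(frozen=True)
class Keypoint:
    """One named anatomical point.

    ``visibility`` follows the common pose-annotation convention:
    0 = not labeled, 1 = labeled but occluded, 2 = labeled and visible.
    OKS and the keypoint losses treat flags 1 and 2 identically (both count
    as visible); only flag 0 is excluded.  ``confidence`` is present iff the
    point belongs to a model prediction.
    """

    name: str
    x: float
    y: float
    visibility: int = 2
    confidence: float | None = None

    def __post_init__(self) -> None:
        if self.name not in KEYPOINT_NAMES:
            raise InvalidInputError(
                f"unknown keypoint name {self.name!r}; expected one of {KEYPOINT_NAMES}"
            )
        if self.visibility not in (0, 1, 2):
            raise InvalidInputError(f"visibility must be 0, 1 or 2, got {self.visibility}")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise InvalidInputError(f"keypoint {self.name!r} has non-finite coordinates")
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise InvalidInputError(
                f"keypoint {self.name!r} confidence {self.confidence} outside [0, 1]"
            )

    @property
    def visible(self) -> bool:
        return self.visibility > 0


@dataclass(frozen=True)
class CrabKeypointSet:
    """The complete 6-point keypoint set of one crab instance.

    All 6 names are always present; a point that was never labeled carries
    visibility 0 (its coordinates are then meaningless and ignored).
    """

    keypoints: tuple[Keypoint, ...]

    def __post_init__(self) -> None:
        names = [kp.name for kp in self.keypoints]
        if sorted(names) != sorted(KEYPOINT_NAMES):
            dupes = {n for n in names if names.count(n) > 1}
            if dupes:
                raise InvalidInputError(f"duplicate keypoint name(s): {sorted(dupes)}")
            missing = set(KEYPOINT_NAMES) - set(names)
            raise InvalidInputError(f"missing keypoint name(s): {sorted(missing)}")
        # canonical storage order
        order = {n: i for i, n in enumerate(KEYPOINT_NAMES)}
        object.__setattr__(
            self, "keypoints", tuple(sorted(self.keypoints, key=lambda k: order[k.name]))
        )

    @classmethod
    def from_partial(cls, points: Iterable[Keypoint]) -> "CrabKeypointSet":
        """Build a full set, filling unlabeled names with visibility-0 points."""
        pts = list(points)
        names = [p.name for p in pts]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise InvalidInputError(f"duplicate keypoint name(s): {sorted(dupes)}")
        for name in KEYPOINT_NAMES:
            if name not in names:
                pts.append(Keypoint(name, 0.0, 0.0, visibility=0))
        return cls(tuple(pts))

    def __getitem__(self, name: str) -> Keypoint:
        for kp in self.keypoints:
            if kp.name == name:
                return kp
        raise KeyError(name)

    def __iter__(self) -> Iterator[Keypoint]:
        return iter(self.keypoints)

    def visible_names(self) -> tuple[str, ...]:
        return tuple(kp.name for kp in self.keypoints if kp.visible)

    def with_replaced(self, **by_name: Keypoint) -> "CrabKeypointSet":
        return CrabKeypointSet(
            tuple(by_name.get(kp.name, kp) for kp in self.keypoints)
        )


@dataclass(frozen=True)
class Annotation:
    """Ground truth for one crab instance in one image."""

    image_id: str
    image_width: int
    image_height: int
    box: BoundingBox
    keypoints: CrabKeypointSet
    class_label: str = "carapace"


@dataclass(frozen=True)
class PredictionRecord:
    """Model output for one detected instance: box + keypoints + scores."""

    image_id: str
    box: BoundingBox
    box_confidence: float
    keypoints: CrabKeypointSet
    class_label: str = "carapace"

    def __post_init__(self) -> None:
        if not (0.0 <= self.box_confidence <= 1.0):
            raise InvalidInputError(f"box_confidence {self.box_confidence} outside [0, 1]")


@dataclass(frozen=True)
class LossWeights:
    """Weights of the five terms of the total training loss.

    Defaults are the published weighting: classification 0.5, box EIoU 7.5,
    distribution focal 1.5, keypoint OKS 15, keypoint confidence 1.0.
    """

    lambda_cls: float = 0.5
    lambda_eiou: float = 7.5
    lambda_dfl: float = 1.5
    lambda_kpts: float = 15.0
    lambda_kpts_conf: float = 1.0

    def __post_init__(self) -> None:
        for name in ("lambda_cls", "lambda_eiou", "lambda_dfl", "lambda_kpts", "lambda_kpts_conf"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")

    def scaled(self, k: float) -> "LossWeights":
        return LossWeights(
            self.lambda_cls * k,
            self.lambda_eiou * k,
            self.lambda_dfl * k,
            self.lambda_kpts * k,
            self.lambda_kpts_conf * k,
        )


def validate_annotation(a: Annotation) -> list[str]:
    """Check an annotation against its invariants.

    Returns a list of human-readable violation descriptions, empty iff the
    annotation is well formed.  Reports, never raises.
    """
    violations: list[str] = []
    b = a.box
    if b.width <= 0:
        violations.append(f"box: degenerate width (x_max={b.x_max} <= x_min={b.x_min})")
    if b.height <= 0:
        violations.append(f"box: degenerate height (y_max={b.y_max} <= y_min={b.y_min})")
    if a.image_width <= 0 or a.image_height <= 0:
        violations.append(
            f"image: non-positive dimensions ({a.image_width} x {a.image_height})"
        )
    if b.width > 0 and b.height > 0:
        if b.x_min < 0 or b.y_min < 0 or b.x_max > a.image_width or b.y_max > a.image_height:
            violations.append(
                f"box: outside image bounds [0, {a.image_width}] x [0, {a.image_height}]"
            )
    for kp in a.keypoints:
        if kp.visible and not (
            0 <= kp.x <= a.image_width and 0 <= kp.y <= a.image_height
        ):
            violations.append(
                f"keypoint {kp.name}: visible but out of bounds at ({kp.x}, {kp.y})"
            )
    return violations


def to_cartesian(kps: CrabKeypointSet, image_height: float) -> CrabKeypointSet:
    """Reporting transform to a bottom-left-origin Cartesian frame.

    Maps y to ``image_height - y``.  Display output only; all internal
    computation stays in the image frame.
    """
    return CrabKeypointSet(
        tuple(replace(kp, y=image_height - kp.y) for kp in kps)
    )
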