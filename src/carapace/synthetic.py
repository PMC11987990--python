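"""Synthetic calibrated crab scenes for offline testing and demos.

A scene emulates the acquisition geometry of a top-down aquaculture
imaging rig: an orange calibration plate of known physical side length on a
dark background, with one or more crabs on it.  The crab body is an ellipse
whose semi-axes realize a known carapace width and length; the six keypoints
are placed analytically on the ellipse (side points at the ends of the width
axis, front/behind at the ends of the length axis, eyes symmetric about the
length axis on the anterior half), so every derived quantity has an exact
ground truth.

The ``thickness_offset_mm`` parameter emulates the systematic difference
between the projected shell outline seen by the camera and the
caliper-measured size caused by the crab's height above the plate: the
recorded physical truth is the projected size plus the offset.  With the
default offset of 0 the pure plate scale recovers truth exactly; a nonzero
offset gives the linear calibration regression a real signal to recover.

Default raster is 750 x 1000 (a quarter of the 3000 x 4000 capture
resolution) to keep tests fast; full-size renders are a config change.
All generator paths are fully deterministic under their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from skimage.color import hsv2rgb, rgb2hsv
from skimage.draw import ellipse as draw_ellipse
from skimage.transform import resize as sk_resize

from .core import (
    FLIP_PAIRS,
    KEYPOINT_NAMES,
    Annotation,
    BoundingBox,
    CrabKeypointSet,
    InvalidInputError,
    Keypoint,
    PredictionRecord,
    validate_annotation,
)

__all__ = [
    "SceneParams",
    "CrabTruth",
    "SyntheticScene",
    "NoiseSpec",
    "AUGMENT_OPS",
    "generate_scene",
    "perturb_predictions",
    "augment",
    "expand_dataset",
]

PLATE_COLOR = (235, 140, 40)  # orange
BACKGROUND_COLOR = (25, 70, 45)  # dark green water/deck
CRAB_COLOR = (55, 75, 50)

AUGMENT_OPS = ("scale_resize", "horizontal_flip", "color_transform")


@dataclass(frozen=True)
class SceneParams:
    """Scene geometry and crab size ranges.

    Carapace width defaults to 50-80 mm with length 0.85-0.95 of width,
    the adult size range of the farmed mitten crabs the imaging rig
    targets.  The plate is 250 mm a side, rendered 500 px wide, giving
    0.5 mm/px.
    """

    image_width: int = 750
    image_height: int = 1000
    plate_side_mm: float = 250.0
    plate_side_px: float | None = None  # default: 2/3 of the short image side
    width_mm_range: tuple[float, float] = (50.0, 80.0)
    length_ratio_range: tuple[float, float] = (0.85, 0.95)
    thickness_offset_mm: float = 0.0
    claw_margin_frac: float = 0.15
    n_crabs: int = 1
    render: bool = True

    @property
    def plate_px(self) -> float:
        if self.plate_side_px is not None:
            return self.plate_side_px
        return (2.0 / 3.0) * min(self.image_width, self.image_height)

    @property
    def mm_per_pixel(self) -> float:
        return self.plate_side_mm / self.plate_px


@dataclass(frozen=True)
class CrabTruth:
    """One generated crab with its physical ground truth."""

    annotation: Annotation
    true_width_mm: float
    true_length_mm: float
    thickness_offset_mm: float


@dataclass(frozen=True)
class SyntheticScene:
    """Rendered scene plus complete ground truth."""

    image: np.ndarray | None
    plate_corners_px: tuple[tuple[float, float], ...]
    plate_side_mm: float
    mm_per_pixel: float
    crabs: tuple[CrabTruth, ...]
    image_width: int
    image_height: int


@dataclass(frozen=True)
class NoiseSpec:
    """Prediction-noise model: Gaussian keypoint displacement, uniform box
    jitter, uniform confidence sampling, Bernoulli visibility dropout."""

    keypoint_sigma_px: float = 0.0
    box_jitter_px: float = 0.0
    confidence_range: tuple[float, float] = (0.8, 1.0)
    dropout_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.keypoint_sigma_px < 0 or self.box_jitter_px < 0:
            raise InvalidInputError("noise magnitudes must be >= 0")
        lo, hi = self.confidence_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise InvalidInputError(f"confidence_range {self.confidence_range} invalid")
        if not (0.0 <= self.dropout_prob <= 1.0):
            raise InvalidInputError(f"dropout_prob {self.dropout_prob} outside [0, 1]")


def _plate_corners(params: SceneParams) -> tuple[tuple[float, float], ...]:
    cx, cy = params.image_width / 2.0, params.image_height / 2.0
    h = params.plate_px / 2.0
    return (
        (cx - h, cy - h),
        (cx + h, cy - h),
        (cx + h, cy + h),
        (cx - h, cy + h),
    )


def _render(params: SceneParams, crabs: Sequence[dict]) -> np.ndarray:
    img = np.empty((params.image_height, params.image_width, 3), dtype=np.uint8)
    img[...] = BACKGROUND_COLOR
    (x0, y0), _, (x1, y1), _ = _plate_corners(params)
    img[int(round(y0)) : int(round(y1)), int(round(x0)) : int(round(x1))] = PLATE_COLOR
    for c in crabs:
        rr, cc = draw_ellipse(
            c["cy"],
            c["cx"],
            c["b_px"],
            c["a_px"],
            shape=img.shape[:2],
            rotation=-c["theta"],
        )
        img[rr, cc] = CRAB_COLOR
    return img


def generate_scene(params: SceneParams | None = None, seed: int = 0) -> SyntheticScene:
    """Generate one calibrated scene; bit-identical for a fixed seed."""
    if params is None:
        params = SceneParams()
    rng = np.random.default_rng(seed)
    mmpp = params.mm_per_pixel
    corners = _plate_corners(params)
    (px0, py0), _, (px1, py1), _ = corners

    crabs: list[CrabTruth] = []
    raster: list[dict] = []
    for i in range(params.n_crabs):
        width_mm = rng.uniform(*params.width_mm_range)
        length_mm = width_mm * rng.uniform(*params.length_ratio_range)
        width_px = width_mm / mmpp
        length_px = length_mm / mmpp
        margin_px = params.claw_margin_frac * width_px
        half_extent = 0.5 * max(width_px, length_px) + margin_px
        if 2 * half_extent > params.plate_px:
            raise InvalidInputError(
                f"crab (width {width_mm:.1f} mm) does not fit on the plate"
            )
        cx = rng.uniform(px0 + half_extent, px1 - half_extent)
        cy = rng.uniform(py0 + half_extent, py1 - half_extent)
        theta = rng.uniform(0.0, 2.0 * math.pi)
        # width axis (left -> right) and front direction, image frame
        ux, uy = math.cos(theta), math.sin(theta)
        vx, vy = math.sin(theta), -math.cos(theta)
        a, b = width_px / 2.0, length_px / 2.0

        def pt(du: float, dv: float) -> tuple[float, float]:
            return (cx + du * ux + dv * vx, cy + du * uy + dv * vy)

        eye_v = 0.85 * b
        eye_u = 0.30 * a
        kps = CrabKeypointSet(
            tuple(
                Keypoint(name, *xy)
                for name, xy in [
                    ("left_eye", pt(-eye_u, eye_v)),
                    ("right_eye", pt(eye_u, eye_v)),
                    ("left_side", pt(-a, 0.0)),
                    ("right_side", pt(a, 0.0)),
                    ("front_side", pt(0.0, b)),
                    ("behind_side", pt(0.0, -b)),
                ]
            )
        )
        ex = math.hypot(a * ux, b * vx) + margin_px
        ey = math.hypot(a * uy, b * vy) + margin_px
        box = BoundingBox(cx - ex, cy - ey, cx + ex, cy + ey)
        ann = Annotation(
            image_id=f"scene{seed}_crab{i}",
            image_width=params.image_width,
            image_height=params.image_height,
            box=box,
            keypoints=kps,
        )
        crabs.append(
            CrabTruth(
                annotation=ann,
                true_width_mm=width_mm + params.thickness_offset_mm,
                true_length_mm=length_mm + params.thickness_offset_mm,
                thickness_offset_mm=params.thickness_offset_mm,
            )
        )
        raster.append({"cx": cx, "cy": cy, "a_px": a, "b_px": b, "theta": theta})

    image = _render(params, raster) if params.render else None
    return SyntheticScene(
        image=image,
        plate_corners_px=corners,
        plate_side_mm=params.plate_side_mm,
        mm_per_pixel=mmpp,
        crabs=tuple(crabs),
        image_width=params.image_width,
        image_height=params.image_height,
    )


def perturb_predictions(scene: SyntheticScene, spec: NoiseSpec) -> list[PredictionRecord]:
    """Noisy model-output records for every crab in the scene."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.confidence_range
    preds: list[PredictionRecord] = []
    for crab in scene.crabs:
        ann = crab.annotation
        points = []
        for name in KEYPOINT_NAMES:
            kp = ann.keypoints[name]
            dx, dy = rng.normal(0.0, spec.keypoint_sigma_px, size=2) if spec.keypoint_sigma_px else (0.0, 0.0)
            dropped = rng.random() < spec.dropout_prob
            conf = float(rng.uniform(lo, hi))
            points.append(
                Keypoint(
                    name,
                    kp.x + float(dx),
                    kp.y + float(dy),
                    visibility=0 if dropped else kp.visibility,
                    confidence=conf,
                )
            )
        j = spec.box_jitter_px
        b = ann.box
        if j > 0:
            d = rng.uniform(-j, j, size=4)
            box = BoundingBox(b.x_min + d[0], b.y_min + d[1], b.x_max + d[2], b.y_max + d[3])
            if not box.is_valid():
                box = b
        else:
            box = b
        preds.append(
            PredictionRecord(
                image_id=ann.image_id,
                box=box,
                box_confidence=float(rng.uniform(lo, hi)),
                keypoints=CrabKeypointSet(tuple(points)),
            )
        )
    return preds


def _flip_annotation(a: Annotation) -> Annotation:
    w = a.image_width
    box = BoundingBox(w - a.box.x_max, a.box.y_min, w - a.box.x_min, a.box.y_max)
    swap = {}
    for left, right in FLIP_PAIRS:
        swap[left], swap[right] = right, left
    points = tuple(
        Keypoint(swap.get(kp.name, kp.name), w - kp.x, kp.y, kp.visibility, kp.confidence)
        for kp in a.keypoints
    )
    return replace(a, box=box, keypoints=CrabKeypointSet(points))


def augment(
    image: np.ndarray,
    annotation: Annotation,
    op: str,
    params: dict | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, Annotation]:
    """One augmentation of an (image, annotation) pair.

    ``scale_resize`` rescales raster and coordinates together (factor drawn
    from ``params['factor']`` or uniformly from 0.6-1.4 under the seed);
    ``horizontal_flip`` mirrors x and swaps the laterally paired labels so
    anatomy stays consistent; ``color_transform`` jitters hue, saturation
    and brightness within bounds that keep the orange plate recognizable,
    leaving the annotation untouched.  Outputs always pass validation.
    """
    params = params or {}
    rng = np.random.default_rng(seed)
    if op == "scale_resize":
        factor = float(params.get("factor", rng.uniform(0.6, 1.4)))
        if factor <= 0:
            raise InvalidInputError(f"scale factor must be > 0, got {factor}")
        new_w = max(1, round(annotation.image_width * factor))
        new_h = max(1, round(annotation.image_height * factor))
        sx = new_w / annotation.image_width
        sy = new_h / annotation.image_height
        out = sk_resize(image, (new_h, new_w), preserve_range=True, anti_aliasing=True)
        out = out.astype(image.dtype)
        b = annotation.box
        box = BoundingBox(b.x_min * sx, b.y_min * sy, b.x_max * sx, b.y_max * sy)
        points = tuple(
            Keypoint(kp.name, kp.x * sx, kp.y * sy, kp.visibility, kp.confidence)
            for kp in annotation.keypoints
        )
        ann = replace(
            annotation,
            image_width=new_w,
            image_height=new_h,
            box=box,
            keypoints=CrabKeypointSet(points),
        )
        return out, ann
    if op == "horizontal_flip":
        return np.flip(image, axis=1).copy(), _flip_annotation(annotation)
    if op == "color_transform":
        hsv = rgb2hsv(image)
        hsv[..., 0] = np.mod(hsv[..., 0] + rng.uniform(-0.03, 0.03), 1.0)
        hsv[..., 1] = np.clip(hsv[..., 1] * rng.uniform(0.9, 1.1), 0.0, 1.0)
        hsv[..., 2] = np.clip(hsv[..., 2] * rng.uniform(0.9, 1.1), 0.0, 1.0)
        out = (hsv2rgb(hsv) * 255).astype(np.uint8)
        return out, annotation
    raise InvalidInputError(f"unknown augmentation op {op!r}; expected one of {AUGMENT_OPS}")


def expand_dataset(
    items: Sequence[tuple[np.ndarray, Annotation]],
    ops: Sequence[str] = AUGMENT_OPS,
    seed: int = 0,
) -> list[tuple[np.ndarray, Annotation]]:
    """Original + one variant per op for every input pair.

    With the default three ops the dataset grows fourfold (1256 source
    images become 5024).  Every output passes annotation validation.
    """
    rng = np.random.default_rng(seed)
    out: list[tuple[np.ndarray, Annotation]] = []
    for image, ann in items:
        out.append((image, ann))
        for op in ops:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            img2, ann2 = augment(image, ann, op, seed=sub_seed)
            if validate_annotation(ann2):
                raise InvalidInputError(
                    f"augmentation {op!r} produced an invalid annotation"
                )
            out.append((img2, ann2))
    return out
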