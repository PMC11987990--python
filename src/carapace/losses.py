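"""Loss stack for box + keypoint detection of crab carapaces.

The box regression term is the EIoU loss: the classical ``1 - IoU`` plus an
explicit centroid-distance penalty and separate width/height penalties, each
normalized by the smallest rectangle enclosing both boxes,

    L_EIoU = (1 - IoU) + rho^2(b, b_gt)/c^2
           + (w - w_gt)^2/c_w^2 + (h - h_gt)^2/c_h^2,

where ``c`` is the enclosing rectangle's diagonal and ``c_w``, ``c_h`` its
width and height.  The keypoint term is the complement of object keypoint
similarity (OKS),

    OKS = sum_n exp(-d_n^2 / (2 s^2 k_n^2)) [v_n > 0] / sum_n [v_n > 0],

with ``d_n`` the pixel distance between predicted and true locations of
keypoint ``n``, ``s`` the square root of the ground-truth box area, ``k_n``
a per-keypoint tolerance, and ``[v_n > 0]`` gating to labeled keypoints.

Classification, keypoint-confidence and distribution-focal terms are the
standard YOLO-family forms (binary cross-entropy and DFL); they complete the
weighted total so it is computable end to end, but carry no novelty here.

All functions are pure forward evaluations; gradient propagation is the
consumer's concern.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .core import (
    KEYPOINT_NAMES,
    BoundingBox,
    CrabKeypointSet,
    InvalidInputError,
    LossWeights,
    UndefinedOKSError,
)

__all__ = [
    "DEFAULT_K",
    "CLAMP_EPS",
    "EIoUBreakdown",
    "OKSParams",
    "LossComponents",
    "iou",
    "eiou_loss",
    "oks",
    "keypoint_loss",
    "keypoint_conf_loss",
    "classification_loss",
    "dfl_loss",
    "total_loss",
    "load_loss_config",
]

#: Default per-keypoint OKS tolerance.  Crab landmarks have no published
#: COCO-style sigmas; a uniform 0.1 keeps OKS interpretable and makes every
#: keypoint contribute equally.
DEFAULT_K: float = 0.1

#: Probabilities are clamped to [CLAMP_EPS, 1 - CLAMP_EPS] before logs so
#: losses stay finite at the boundary.
CLAMP_EPS: float = 1e-7


@dataclass(frozen=True)
class EIoUBreakdown:
    """The three additive components of the EIoU loss and their sum."""

    l_iou: float
    l_dis: float
    l_asp: float

    @property
    def total(self) -> float:
        return self.l_iou + self.l_dis + self.l_asp


@dataclass(frozen=True)
class OKSParams:
    """Per-keypoint OKS tolerances k_n (one entry per schema name, > 0)."""

    per_keypoint_k: Mapping[str, float] = field(
        default_factory=lambda: {name: DEFAULT_K for name in KEYPOINT_NAMES}
    )

    def __post_init__(self) -> None:
        keys = set(self.per_keypoint_k)
        if keys != set(KEYPOINT_NAMES):
            raise InvalidInputError(
                f"per_keypoint_k must have exactly the 6 schema names; got {sorted(keys)}"
            )
        for name, k in self.per_keypoint_k.items():
            if not (k > 0):
                raise InvalidInputError(f"k for {name!r} must be > 0, got {k}")


@dataclass(frozen=True)
class LossComponents:
    """Per-instance raw loss values entering the weighted total."""

    cls: float
    eiou: float
    dfl: float
    kpts: float
    kpts_conf: float

    def __post_init__(self) -> None:
        for name in ("cls", "eiou", "dfl", "kpts", "kpts_conf"):
            v = getattr(self, name)
            if not (v >= 0):
                raise InvalidInputError(f"loss component {name} must be >= 0, got {v}")


def _require_valid(box: BoundingBox, role: str) -> None:
    if not box.is_valid():
        raise InvalidInputError(f"{role} box is degenerate: {box}")


def iou(box_a: BoundingBox, box_b: BoundingBox) -> float:
    """Intersection over union of two valid boxes, in [0, 1]."""
    _require_valid(box_a, "first")
    _require_valid(box_b, "second")
    ix = min(box_a.x_max, box_b.x_max) - max(box_a.x_min, box_b.x_min)
    iy = min(box_a.y_max, box_b.y_max) - max(box_a.y_min, box_b.y_min)
    inter = max(ix, 0.0) * max(iy, 0.0)
    union = box_a.area + box_b.area - inter
    return inter / union


def eiou_loss(pred: BoundingBox, target: BoundingBox) -> EIoUBreakdown:
    """EIoU loss between a predicted and a target box.

    Returns the three-way breakdown; ``total`` is their exact sum and is 0
    iff the boxes are identical.
    """
    _require_valid(pred, "pred")
    _require_valid(target, "target")
    l_iou = 1.0 - iou(pred, target)

    cw = max(pred.x_max, target.x_max) - min(pred.x_min, target.x_min)
    ch = max(pred.y_max, target.y_max) - min(pred.y_min, target.y_min)
    c2 = cw * cw + ch * ch

    (bx, by), (gx, gy) = pred.center, target.center
    l_dis = ((bx - gx) ** 2 + (by - gy) ** 2) / c2

    l_asp = (pred.width - target.width) ** 2 / (cw * cw) + (
        pred.height - target.height
    ) ** 2 / (ch * ch)
    return EIoUBreakdown(l_iou=l_iou, l_dis=l_dis, l_asp=l_asp)


def oks(
    pred: CrabKeypointSet,
    target: CrabKeypointSet,
    box_area: float,
    params: OKSParams | None = None,
) -> float:
    """Object keypoint similarity between predicted and true keypoint sets.

    ``box_area`` is the area of the ground-truth detection box; its square
    root is the object scale ``s``.  Keypoints with target visibility 0
    contribute to neither numerator nor denominator.

    Raises
    ------
    UndefinedOKSError
        If no target keypoint is visible.  Callers must filter such
        instances before scoring.
    """
    if params is None:
        params = OKSParams()
    if not (box_area > 0):
        raise InvalidInputError(f"box_area must be > 0, got {box_area}")
    s2 = float(box_area)
    num = 0.0
    n_vis = 0
    for name in KEYPOINT_NAMES:
        t = target[name]
        if not t.visible:
            continue
        p = pred[name]
        d2 = (p.x - t.x) ** 2 + (p.y - t.y) ** 2
        k = params.per_keypoint_k[name]
        num += math.exp(-d2 / (2.0 * s2 * k * k))
        n_vis += 1
    if n_vis == 0:
        raise UndefinedOKSError("no visible target keypoints; OKS is undefined")
    return num / n_vis


def keypoint_loss(
    pred: CrabKeypointSet,
    target: CrabKeypointSet,
    box_area: float,
    params: OKSParams | None = None,
) -> float:
    """Keypoint localization loss ``1 - OKS``; 0 iff prediction is perfect."""
    return 1.0 - oks(pred, target, box_area, params)


def _bce(p: float, y: float) -> float:
    p = min(max(p, CLAMP_EPS), 1.0 - CLAMP_EPS)
    return -(y * math.log(p) + (1.0 - y) * math.log(1.0 - p))


def keypoint_conf_loss(pred: CrabKeypointSet, target: CrabKeypointSet) -> float:
    """BCE between predicted keypoint confidence and the visibility indicator.

    The target for keypoint ``n`` is 1 if its ground-truth visibility flag is
    positive, else 0; the loss is averaged over the 6 keypoints.
    """
    total = 0.0
    for name in KEYPOINT_NAMES:
        p = pred[name].confidence
        if p is None:
            raise InvalidInputError(f"prediction keypoint {name!r} carries no confidence")
        if not (0.0 <= p <= 1.0):
            raise InvalidInputError(f"confidence {p} for {name!r} outside [0, 1]")
        y = 1.0 if target[name].visible else 0.0
        total += _bce(p, y)
    return total / len(KEYPOINT_NAMES)


def classification_loss(pred_score: float, target: int) -> float:
    """Binary cross-entropy of the single-class objectness score."""
    if not (0.0 <= pred_score <= 1.0):
        raise InvalidInputError(f"pred_score {pred_score} outside [0, 1]")
    if target not in (0, 1):
        raise InvalidInputError(f"target must be 0 or 1, got {target}")
    return _bce(pred_score, float(target))


def dfl_loss(pred_distribution: Sequence[float], target: float) -> float:
    """Distribution focal loss for one box-edge coordinate.

    ``pred_distribution`` is a probability vector over integer bins
    0..m-1; ``target`` is the continuous bin coordinate.  The loss is the
    cross-entropy against the two bracketing bins weighted by proximity,

        DFL = -((ceil(t) - t) ln p_floor(t) + (t - floor(t)) ln p_ceil(t)),

    minimized when the mass concentrates on the bins bracketing ``t``.
    """
    p = np.asarray(pred_distribution, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise InvalidInputError("pred_distribution must be a 1-D vector of >= 2 bins")
    if abs(p.sum() - 1.0) > 1e-6:
        raise InvalidInputError(f"pred_distribution sums to {p.sum()}, not 1")
    t = float(target)
    if not (0.0 <= t <= p.size - 1):
        raise InvalidInputError(f"target {t} outside bin range [0, {p.size - 1}]")
    lo = math.floor(t)
    hi = math.ceil(t)
    p_lo = min(max(p[lo], CLAMP_EPS), 1.0)
    if lo == hi:
        return -math.log(p_lo)
    p_hi = min(max(p[hi], CLAMP_EPS), 1.0)
    return -((hi - t) * math.log(p_lo) + (t - lo) * math.log(p_hi))


def total_loss(
    components: LossComponents | Sequence[LossComponents],
    weights: LossWeights | None = None,
) -> float:
    """Weighted total loss, summed over instances.

    ``components`` may be a single per-instance record or a sequence of
    them; the total is linear in both the weights and the instances.
    """
    if weights is None:
        weights = LossWeights()
    if isinstance(components, LossComponents):
        components = [components]
    total = 0.0
    for c in components:
        total += (
            weights.lambda_cls * c.cls
            + weights.lambda_eiou * c.eiou
            + weights.lambda_dfl * c.dfl
            + weights.lambda_kpts * c.kpts
            + weights.lambda_kpts_conf * c.kpts_conf
        )
    return total


def load_loss_config(path: str | Path) -> tuple[LossWeights, OKSParams]:
    """Read loss weights and per-keypoint k_n from a YAML or JSON file.

    Recognized keys: ``weights`` (mapping with the five lambda_* entries)
    and ``per_keypoint_k`` (mapping keypoint name -> k).  Missing sections
    fall back to defaults.
    """
    text = Path(path).read_text()
    doc = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
    if doc is None:
        doc = {}
    weights = LossWeights(**doc.get("weights", {}))
    if "per_keypoint_k" in doc:
        params = OKSParams(dict(doc["per_keypoint_k"]))
    else:
        params = OKSParams()
    return weights, params
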