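"""Annotation format handling: Labelme JSON in, YOLO-pose txt out.

A Labelme document contributes one rectangle shape labeled ``carapace`` plus
up to six named point shapes per instance; instances are distinguished by
``group_id`` when present, with a single-instance fallback when all group
ids are absent (the field's images contain one crab).

The YOLO-pose line format is::

    class cx cy w h  kx1 ky1 v1  ...  kx6 ky6 v6

with box center/size and keypoint coordinates normalized by the image
dimensions, 6 decimal places, and keypoints in the fixed schema order
(left_eye, right_eye, left_side, right_side, front_side, behind_side).
An unlabeled keypoint (visibility 0) is serialized as ``0 0 0``.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .core import (
    FLIP_PAIRS,
    KEYPOINT_NAMES,
    Annotation,
    BoundingBox,
    CrabKeypointSet,
    InvalidInputError,
    Keypoint,
    validate_annotation,
)

__all__ = [
    "LabelmeFormatError",
    "YoloFormatError",
    "read_labelme",
    "write_yolo_pose",
    "read_yolo_pose",
    "split_dataset",
    "dataset_yaml",
]

N_FIELDS = 5 + 3 * len(KEYPOINT_NAMES)  # 23

BOX_LABEL = "carapace"


class LabelmeFormatError(InvalidInputError):
    """A Labelme document violates the expected labeling schema."""


class YoloFormatError(InvalidInputError):
    """A YOLO-pose line is malformed; message carries the line number."""


def read_labelme(doc: dict | str | Path) -> list[Annotation]:
    """Parse a Labelme document (dict, JSON text, or path) into annotations.

    Rectangle shapes labeled ``carapace`` become boxes; point shapes with
    schema labels become keypoints with visibility 2.  Shapes sharing a
    ``group_id`` form one instance; if every group_id is absent the whole
    document is a single instance.
    """
    if isinstance(doc, (str, Path)):
        text = str(doc)
        if not text.lstrip().startswith("{"):
            text = Path(doc).read_text()
        doc = json.loads(text)
    try:
        width = int(doc["imageWidth"])
        height = int(doc["imageHeight"])
        shapes = doc["shapes"]
    except KeyError as e:
        raise LabelmeFormatError(f"document missing required field {e}") from e
    image_id = str(Path(doc.get("imagePath", "image")).stem)

    groups: dict[object, dict] = {}
    any_group = any(s.get("group_id") is not None for s in shapes)
    for s in shapes:
        gid = s.get("group_id") if any_group else 0
        g = groups.setdefault(gid, {"box": None, "points": []})
        stype = s.get("shape_type")
        label = s.get("label")
        if stype == "rectangle":
            if label != BOX_LABEL:
                raise LabelmeFormatError(f"unexpected rectangle label {label!r}")
            pts = s.get("points", [])
            if len(pts) != 2:
                raise LabelmeFormatError(
                    f"rectangle must have 2 corner points, got {len(pts)}"
                )
            (x1, y1), (x2, y2) = pts
            g["box"] = BoundingBox(min(x1, x2), min(y1, y2), max(x1, x2), max(y1, y2))
        elif stype == "point":
            if label not in KEYPOINT_NAMES:
                raise LabelmeFormatError(f"unknown keypoint label {label!r}")
            if any(p.name == label for p in g["points"]):
                raise LabelmeFormatError(
                    f"duplicate keypoint label {label!r} in group {gid!r}"
                )
            (x, y), = s.get("points", [(None, None)])
            g["points"].append(Keypoint(label, float(x), float(y), visibility=2))
        else:
            raise LabelmeFormatError(f"unsupported shape_type {stype!r}")

    annotations = []
    for gid in sorted(groups, key=lambda g: (g is None, g)):
        g = groups[gid]
        if g["box"] is None:
            raise LabelmeFormatError(f"group {gid!r} has no carapace rectangle")
        annotations.append(
            Annotation(
                image_id=image_id,
                image_width=width,
                image_height=height,
                box=g["box"],
                keypoints=CrabKeypointSet.from_partial(g["points"]),
            )
        )
    return annotations


def write_yolo_pose(
    annotations: Sequence[Annotation], image_width: int, image_height: int
) -> list[str]:
    """Serialize annotations to YOLO-pose lines (one per instance)."""
    lines = []
    for a in annotations:
        problems = validate_annotation(a)
        if problems:
            raise InvalidInputError(
                f"annotation {a.image_id!r} fails validation: " + "; ".join(problems)
            )
        cx, cy = a.box.center
        fields = [
            "0",
            f"{cx / image_width:.6f}",
            f"{cy / image_height:.6f}",
            f"{a.box.width / image_width:.6f}",
            f"{a.box.height / image_height:.6f}",
        ]
        for name in KEYPOINT_NAMES:
            kp = a.keypoints[name]
            if kp.visibility == 0:
                fields += ["0.000000", "0.000000", "0"]
            else:
                fields += [
                    f"{kp.x / image_width:.6f}",
                    f"{kp.y / image_height:.6f}",
                    str(kp.visibility),
                ]
        lines.append(" ".join(fields))
    return lines


def read_yolo_pose(
    lines: Iterable[str], image_width: int, image_height: int, image_id: str = "image"
) -> list[Annotation]:
    """Parse YOLO-pose lines back into annotations (inverse of the writer
    up to 1e-6 in normalized units)."""
    annotations = []
    for lineno, raw in enumerate(lines, start=1):
        raw = raw.strip()
        if not raw:
            continue
        fields = raw.split()
        if len(fields) != N_FIELDS:
            raise YoloFormatError(
                f"line {lineno}: expected {N_FIELDS} fields, got {len(fields)}"
            )
        try:
            vals = [float(f) for f in fields]
        except ValueError as e:
            raise YoloFormatError(f"line {lineno}: non-numeric field ({e})") from e
        _, cx, cy, w, h = vals[:5]
        box = BoundingBox.from_center(
            cx * image_width, cy * image_height, w * image_width, h * image_height
        )
        points = []
        for i, name in enumerate(KEYPOINT_NAMES):
            kx, ky, v = vals[5 + 3 * i : 8 + 3 * i]
            v = int(v)
            if v not in (0, 1, 2):
                raise YoloFormatError(f"line {lineno}: visibility flag {v} not in 0..2")
            points.append(
                Keypoint(name, kx * image_width, ky * image_height, visibility=v)
            )
        annotations.append(
            Annotation(
                image_id=image_id,
                image_width=image_width,
                image_height=image_height,
                box=box,
                keypoints=CrabKeypointSet(tuple(points)),
            )
        )
    return annotations


def split_dataset(
    image_ids: Sequence[str], train_fraction: float = 0.9, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Deterministic shuffled train/validation split.

    The validation set receives ``floor(n * (1 - train_fraction))`` items
    (so 5024 images at the default 9:1 ratio split 4522/502); the split is
    a disjoint cover, reproducible under ``seed``.
    """
    if not image_ids:
        raise InvalidInputError("image_ids must be nonempty")
    if not (0.0 < train_fraction < 1.0):
        raise InvalidInputError(f"train_fraction must be in (0, 1), got {train_fraction}")
    n = len(image_ids)
    # guard against binary representation of the fraction (10 * 0.1 != 1.0)
    n_val = math.floor(n * (1.0 - train_fraction) + 1e-9)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    val = [image_ids[i] for i in perm[:n_val]]
    train = [image_ids[i] for i in perm[n_val:]]
    return train, val


def dataset_yaml(
    path_root: str = ".", train: str = "images/train", val: str = "images/val"
) -> str:
    """Companion dataset YAML: keypoint order, flip pairs, single class."""
    flip_idx = list(range(len(KEYPOINT_NAMES)))
    name_to_i = {n: i for i, n in enumerate(KEYPOINT_NAMES)}
    for a, b in FLIP_PAIRS:
        flip_idx[name_to_i[a]], flip_idx[name_to_i[b]] = name_to_i[b], name_to_i[a]
    doc = {
        "path": path_root,
        "train": train,
        "val": val,
        "names": {0: BOX_LABEL},
        "kpt_shape": [len(KEYPOINT_NAMES), 3],
        "keypoint_names": list(KEYPOINT_NAMES),
        "flip_idx": flip_idx,
    }
    return yaml.safe_dump(doc, sort_keys=False)
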