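import math

import numpy as np
import pytest

from carapace.core import (
    KEYPOINT_NAMES,
    Annotation,
    BoundingBox,
    CrabKeypointSet,
    Keypoint,
)


def make_keypoints(coords=None, visibility=None, confidence=None):
    """Build a full 6-point set from a name -> (x, y) mapping (defaults to a
    spread-out layout), with optional per-name visibility/confidence."""
    default = {
        "left_eye": (40.0, 20.0),
        "right_eye": (60.0, 20.0),
        "left_side": (20.0, 50.0),
        "right_side": (80.0, 50.0),
        "front_side": (50.0, 10.0),
        "behind_side": (50.0, 90.0),
    }
    coords = {**default, **(coords or {})}
    visibility = visibility or {}
    confidence = confidence or {}
    return CrabKeypointSet(
        tuple(
            Keypoint(
                name,
                *coords[name],
                visibility=visibility.get(name, 2),
                confidence=confidence.get(name),
            )
            for name in KEYPOINT_NAMES
        )
    )


def make_annotation(image_id="img0", box=None, kps=None, w=100, h=100):
    return Annotation(
        image_id=image_id,
        image_width=w,
        image_height=h,
        box=box or BoundingBox(10.0, 5.0, 90.0, 95.0),
        keypoints=kps or make_keypoints(),
    )


@pytest.fixture
def keypoints():
    return make_keypoints()


@pytest.fixture
def annotation():
    return make_annotation()


def random_box(rng, lo=0.0, hi=100.0, min_size=1.0):
    x = np.sort(rng.uniform(lo, hi, 2))
    y = np.sort(rng.uniform(lo, hi, 2))
    return BoundingBox(x[0], y[0], x[0] + max(x[1] - x[0], min_size), y[0] + max(y[1] - y[0], min_size))


def assert_annotations_close(a, b, tol=1e-9):
    """Structural equality with a floating-point tolerance on coordinates."""
    assert a.image_id == b.image_id
    assert (a.image_width, a.image_height) == (b.image_width, b.image_height)
    for attr in ("x_min", "y_min", "x_max", "y_max"):
        assert getattr(a.box, attr) == pytest.approx(getattr(b.box, attr), abs=tol)
    for ka, kb in zip(a.keypoints, b.keypoints):
        assert ka.name == kb.name
        assert ka.visibility == kb.visibility
        assert ka.x == pytest.approx(kb.x, abs=tol)
        assert ka.y == pytest.approx(kb.y, abs=tol)


def ap_grid_oracle(flags, n_truth, grid=20000):
    """Numeric-integration AP oracle: interpolated precision (max precision
    at recall >= r) averaged over a dense midpoint grid on (0, 1)."""
    flags = np.asarray(flags, dtype=float)
    tp = np.cumsum(flags)
    fp = np.cumsum(1.0 - flags)
    recall = tp / n_truth
    precision = tp / (tp + fp)
    suffix_max = np.maximum.accumulate(precision[::-1])[::-1]
    rs = (np.arange(grid) + 0.5) / grid
    idx = np.searchsorted(recall, rs - 1e-12, side="left")
    inside = idx < len(recall)
    vals = np.where(inside, suffix_max[np.minimum(idx, len(recall) - 1)], 0.0)
    return float(vals.mean())


def rasterized_iou(a, b, step=0.01):
    """Grid-counting IoU oracle: count cells of side `step` whose centers
    fall inside each box, over the joint bounding region."""
    x0 = min(a.x_min, b.x_min)
    x1 = max(a.x_max, b.x_max)
    y0 = min(a.y_min, b.y_min)
    y1 = max(a.y_max, b.y_max)
    xs = np.arange(x0 + step / 2, x1, step)
    ys = np.arange(y0 + step / 2, y1, step)
    X, Y = np.meshgrid(xs, ys, sparse=True)
    in_a = (X >= a.x_min) & (X <= a.x_max) & (Y >= a.y_min) & (Y <= a.y_max)
    in_b = (X >= b.x_min) & (X <= b.x_max) & (Y >= b.y_min) & (Y <= b.y_max)
    inter = np.count_nonzero(in_a & in_b)
    union = np.count_nonzero(in_a | in_b)
    return inter / union
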