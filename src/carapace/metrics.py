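"""Detection and keypoint evaluation.

Boxes are scored with precision/recall (as percentages) and average
precision over the confidence-ranked precision-recall curve; mAP is
reported at IoU 0.5 and averaged over the 0.50:0.05:0.95 grid.  There is a
single object class, so mAP coincides with AP.

Keypoints are scored per landmark: each visible keypoint contributes the
Gaussian similarity term exp(-d^2 / (2 s^2 k^2)); terms below an exclusion
threshold (default 0.5) are dropped and counted, and the survivors are
summarized by per-keypoint mean and sample standard deviation, the layout
used for the published keypoint-reliability table.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import (
    KEYPOINT_NAMES,
    Annotation,
    CrabKeypointSet,
    InvalidInputError,
    PredictionRecord,
    UndefinedMetricError,
)
from .losses import OKSParams, iou

__all__ = [
    "MatchResult",
    "PRCurve",
    "KeypointOKSReport",
    "match_detections",
    "precision_recall",
    "average_precision",
    "map_over_thresholds",
    "MAP_50_95_GRID",
    "keypoint_oks_report",
    "report_to_json",
    "report_to_text",
]

#: The "50-95" IoU threshold grid: 0.50 to 0.95 inclusive in steps of 0.05.
MAP_50_95_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


@dataclass(frozen=True)
class MatchResult:
    """Outcome of greedy box matching at one IoU threshold."""

    tp: int
    fp: int
    fn: int
    matched_pairs: tuple[tuple[PredictionRecord, Annotation, float], ...]


@dataclass(frozen=True)
class PRCurve:
    """Confidence-ranked precision-recall sweep with its area (AP)."""

    thresholds: tuple[float, ...]
    precision: tuple[float, ...]
    recall: tuple[float, ...]
    ap: float


@dataclass(frozen=True)
class KeypointOKSReport:
    """Per-keypoint similarity statistics after sub-threshold exclusion.

    A keypoint with no surviving terms has no entry in the mean/std maps;
    ``overall_mean`` averages the per-keypoint means that are present.
    """

    per_keypoint_mean: Mapping[str, float]
    per_keypoint_std: Mapping[str, float]
    overall_mean: float
    n_excluded: int


def _ranked(preds: Sequence[PredictionRecord], truths: Sequence[Annotation]):
    """Predictions in evaluation order: confidence desc, then best achievable
    IoU desc (tie-break), then input order."""
    best_iou = []
    for p in preds:
        cands = [iou(p.box, t.box) for t in truths if t.image_id == p.image_id]
        best_iou.append(max(cands, default=0.0))
    order = sorted(
        range(len(preds)), key=lambda i: (-preds[i].box_confidence, -best_iou[i], i)
    )
    return [preds[i] for i in order]


def _greedy_flags(
    preds: Sequence[PredictionRecord],
    truths: Sequence[Annotation],
    iou_threshold: float,
):
    """Greedy one-to-one matching over ranked predictions.

    Returns (tp_flags aligned with the ranked prediction list, ranked preds,
    matches as (pred, truth, iou))."""
    if not (0.0 < iou_threshold < 1.0):
        raise InvalidInputError(f"iou_threshold must be in (0, 1), got {iou_threshold}")
    ranked = _ranked(preds, truths)
    taken = [False] * len(truths)
    tp_flags: list[bool] = []
    matches: list[tuple[PredictionRecord, Annotation, float]] = []
    for p in ranked:
        best_j, best = -1, -1.0
        for j, t in enumerate(truths):
            if taken[j] or t.image_id != p.image_id:
                continue
            v = iou(p.box, t.box)
            if v > best:
                best, best_j = v, j
        if best_j >= 0 and best >= iou_threshold:
            taken[best_j] = True
            tp_flags.append(True)
            matches.append((p, truths[best_j], best))
        else:
            tp_flags.append(False)
    return tp_flags, ranked, matches


def match_detections(
    preds: Sequence[PredictionRecord],
    truths: Sequence[Annotation],
    iou_threshold: float,
) -> MatchResult:
    """Match predictions to ground truth greedily by descending confidence.

    A prediction is a true positive iff its best-IoU unmatched truth (in the
    same image) reaches the threshold; each truth is matched at most once.
    Remaining predictions are false positives, unmatched truths false
    negatives.
    """
    tp_flags, _, matches = _greedy_flags(preds, truths, iou_threshold)
    tp = sum(tp_flags)
    return MatchResult(
        tp=tp, fp=len(preds) - tp, fn=len(truths) - tp, matched_pairs=tuple(matches)
    )


def precision_recall(m: MatchResult) -> tuple[float, float]:
    """Precision and recall as percentages: TP/(TP+FP) and TP/(TP+FN) x 100.

    Raises :class:`UndefinedMetricError` on a zero denominator; an undefined
    metric is reported absent, never as 0.
    """
    if m.tp + m.fp == 0:
        raise UndefinedMetricError("precision undefined: no predictions")
    if m.tp + m.fn == 0:
        raise UndefinedMetricError("recall undefined: no ground-truth instances")
    return (100.0 * m.tp / (m.tp + m.fp), 100.0 * m.tp / (m.tp + m.fn))


def _ap_from_flags(tp_flags: Sequence[bool], n_truth: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Precision/recall arrays and all-points interpolated AP from ranked
    correctness flags."""
    flags = np.asarray(tp_flags, dtype=float)
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(1.0 - flags)
    recall = tp_cum / n_truth
    precision = tp_cum / (tp_cum + fp_cum)
    # precision envelope: running max from the right
    env = np.maximum.accumulate(precision[::-1])[::-1]
    prev_r = 0.0
    ap = 0.0
    for r, p in zip(recall, env):
        ap += (r - prev_r) * p
        prev_r = r
    return precision, recall, float(ap)


def average_precision(
    preds: Sequence[PredictionRecord],
    truths: Sequence[Annotation],
    iou_threshold: float,
) -> PRCurve:
    """AP by all-points (continuous) interpolation of the precision envelope.

    Predictions are swept in descending confidence; at each rank the
    cumulative precision and recall are recorded, precision is replaced by
    its right-to-left running maximum, and AP is the area under the
    resulting step function.
    """
    if not truths:
        raise UndefinedMetricError("average precision undefined: no ground truth")
    tp_flags, ranked, _ = _greedy_flags(preds, truths, iou_threshold)
    if not preds:
        return PRCurve(thresholds=(), precision=(), recall=(), ap=0.0)
    precision, recall, ap = _ap_from_flags(tp_flags, len(truths))
    return PRCurve(
        thresholds=tuple(p.box_confidence for p in ranked),
        precision=tuple(precision),
        recall=tuple(recall),
        ap=ap,
    )


def map_over_thresholds(
    preds: Sequence[PredictionRecord],
    truths: Sequence[Annotation],
    thresholds: Sequence[float] = MAP_50_95_GRID,
) -> tuple[float, float]:
    """(mAP50, mAP50-95) as percentages.

    mAP50 is AP at IoU 0.5; mAP50-95 averages AP over ``thresholds``
    (default the 10-point 0.50:0.05:0.95 grid).  Single class, so mAP = AP.
    """
    for t in thresholds:
        if not (0.0 < t < 1.0):
            raise InvalidInputError(f"threshold {t} outside (0, 1)")
    map50 = average_precision(preds, truths, 0.5).ap * 100.0
    aps = [average_precision(preds, truths, t).ap for t in thresholds]
    return map50, float(np.mean(aps)) * 100.0


def keypoint_oks_report(
    pairs: Sequence[tuple[CrabKeypointSet, CrabKeypointSet, float]],
    params: OKSParams | None = None,
    exclusion_threshold: float = 0.5,
) -> KeypointOKSReport:
    """Per-keypoint similarity statistics over matched instances.

    ``pairs`` holds (predicted keypoints, true keypoints, truth box area)
    triples.  For every visible true keypoint the Gaussian similarity term
    exp(-d^2/(2 s^2 k^2)) is computed; terms below ``exclusion_threshold``
    are excluded and counted in ``n_excluded``.  Means and sample standard
    deviations (n-1 denominator; 0.0 for a single surviving term) are
    reported per keypoint, plus the unweighted mean of the per-keypoint
    means.
    """
    if not pairs:
        raise InvalidInputError("at least one (pred, truth, area) pair is required")
    if params is None:
        params = OKSParams()
    terms: dict[str, list[float]] = {name: [] for name in KEYPOINT_NAMES}
    n_excluded = 0
    for pred, truth, box_area in pairs:
        if not (box_area > 0):
            raise InvalidInputError(f"box_area must be > 0, got {box_area}")
        for name in KEYPOINT_NAMES:
            t = truth[name]
            if not t.visible:
                continue
            p = pred[name]
            d2 = (p.x - t.x) ** 2 + (p.y - t.y) ** 2
            k = params.per_keypoint_k[name]
            term = math.exp(-d2 / (2.0 * box_area * k * k))
            if term < exclusion_threshold:
                n_excluded += 1
            else:
                terms[name].append(term)
    means: dict[str, float] = {}
    stds: dict[str, float] = {}
    for name, vals in terms.items():
        if not vals:
            continue
        arr = np.asarray(vals)
        means[name] = float(arr.mean())
        stds[name] = float(arr.std(ddof=1)) if len(vals) > 1 else 0.0
    if not means:
        raise UndefinedMetricError("all keypoint terms excluded; report undefined")
    overall = float(np.mean(list(means.values())))
    return KeypointOKSReport(
        per_keypoint_mean=means,
        per_keypoint_std=stds,
        overall_mean=overall,
        n_excluded=n_excluded,
    )


def report_to_json(report: KeypointOKSReport) -> str:
    return json.dumps(
        {
            "per_keypoint_mean": dict(report.per_keypoint_mean),
            "per_keypoint_std": dict(report.per_keypoint_std),
            "overall_mean": report.overall_mean,
            "n_excluded": report.n_excluded,
        },
        indent=2,
        sort_keys=True,
    )


def report_to_text(report: KeypointOKSReport) -> str:
    """Plain-text table: keypoint names as columns, mean and std as rows."""
    cols = [n for n in KEYPOINT_NAMES if n in report.per_keypoint_mean]
    width = max(len(c) for c in cols + ["Keypoints"]) + 2
    header = "Keypoints".ljust(width) + "".join(c.ljust(width) for c in cols)
    mean_row = "Mean".ljust(width) + "".join(
        f"{report.per_keypoint_mean[c]:.3f}".ljust(width) for c in cols
    )
    std_row = "Std".ljust(width) + "".join(
        f"{report.per_keypoint_std[c]:.3f}".ljust(width) for c in cols
    )
    footer = (
        f"Overall mean OKS: {report.overall_mean:.4f} "
        f"({report.overall_mean * 100:.2f}%); excluded terms: {report.n_excluded}"
    )
    return "\n".join([header, mean_row, std_row, footer])
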