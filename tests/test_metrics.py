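import itertools
import math

import numpy as np
import pytest

from carapace.core import (
    KEYPOINT_NAMES,
    BoundingBox,
    InvalidInputError,
    PredictionRecord,
    UndefinedMetricError,
)
from carapace.losses import OKSParams
from carapace.metrics import (
    MAP_50_95_GRID,
    MatchResult,
    average_precision,
    keypoint_oks_report,
    map_over_thresholds,
    match_detections,
    precision_recall,
    report_to_text,
)
from conftest import ap_grid_oracle, make_annotation, make_keypoints


def boxed_truth(i, image_id="img0"):
    """Ground-truth instances laid out on a disjoint grid."""
    x = 100.0 * i
    return make_annotation(
        image_id=image_id, box=BoundingBox(x + 10, 10, x + 60, 60), w=10_000, h=100
    )


def pred_for(truth, conf, iou_offset=0.0, image_id=None):
    """A prediction over `truth`'s box, optionally shifted to lower IoU."""
    b = truth.box
    box = BoundingBox(b.x_min + iou_offset, b.y_min, b.x_max + iou_offset, b.y_max)
    return PredictionRecord(
        image_id=image_id or truth.image_id,
        box=box,
        box_confidence=conf,
        keypoints=truth.keypoints,
    )


def pattern_preds(truths, flags, confs=None):
    """One prediction per flag: True -> exact copy of the next unused truth,
    False -> a far-away false positive."""
    confs = confs or np.linspace(0.95, 0.5, len(flags))
    preds = []
    t_iter = iter(truths)
    for i, (flag, conf) in enumerate(zip(flags, confs)):
        if flag:
            preds.append(pred_for(next(t_iter), float(conf)))
        else:
            far = BoundingBox(9000.0 + 10 * i, 80.0, 9005.0 + 10 * i, 90.0)
            preds.append(
                PredictionRecord(
                    image_id=truths[0].image_id,
                    box=far,
                    box_confidence=float(conf),
                    keypoints=truths[0].keypoints,
                )
            )
    return preds


class TestMatching:
    def test_perfect_predictions(self):
        truths = [boxed_truth(i) for i in range(4)]
        preds = [pred_for(t, 1.0) for t in truths]
        m = match_detections(preds, truths, 0.5)
        assert (m.tp, m.fp, m.fn) == (4, 0, 0)
        assert len(m.matched_pairs) == m.tp

    def test_no_predictions(self):
        truths = [boxed_truth(i) for i in range(3)]
        m = match_detections([], truths, 0.5)
        assert (m.tp, m.fp, m.fn) == (0, 0, 3)

    def test_two_predictions_one_truth_greedy_by_confidence(self):
        truth = boxed_truth(0)
        p_hi = pred_for(truth, 0.9, iou_offset=2.0)   # higher IoU, higher conf
        p_lo = pred_for(truth, 0.8, iou_offset=6.0)
        m = match_detections([p_lo, p_hi], [truth], 0.5)
        assert (m.tp, m.fp, m.fn) == (1, 1, 0)
        assert m.matched_pairs[0][0] is p_hi

    def test_truth_matched_at_most_once_each_image(self):
        truths = [boxed_truth(0, "a"), boxed_truth(0, "b")]
        preds = [pred_for(truths[0], 0.9), pred_for(truths[1], 0.8)]
        m = match_detections(preds, truths, 0.5)
        assert (m.tp, m.fp, m.fn) == (2, 0, 0)
        # cross-image match is impossible even with identical geometry
        m2 = match_detections([pred_for(truths[0], 0.9, image_id="c")], truths, 0.5)
        assert (m2.tp, m2.fp, m2.fn) == (0, 1, 2)


class TestPrecisionRecall:
    def test_printed_formula_arithmetic(self):
        m = MatchResult(tp=8, fp=2, fn=2, matched_pairs=())
        assert precision_recall(m) == (80.0, 80.0)

    def test_perfect_detector(self):
        m = MatchResult(tp=5, fp=0, fn=0, matched_pairs=())
        assert precision_recall(m) == (100.0, 100.0)

    def test_fp_only_detector(self):
        m = MatchResult(tp=0, fp=4, fn=3, matched_pairs=())
        assert precision_recall(m) == (0.0, 0.0)

    def test_undefined_metrics_raise(self):
        with pytest.raises(UndefinedMetricError, match="precision"):
            precision_recall(MatchResult(0, 0, 3, ()))
        with pytest.raises(UndefinedMetricError, match="recall"):
            precision_recall(MatchResult(0, 2, 0, ()))


class TestAveragePrecision:
    def test_all_correct_gives_one(self):
        truths = [boxed_truth(i) for i in range(5)]
        preds = [pred_for(t, c) for t, c in zip(truths, np.linspace(0.9, 0.5, 5))]
        assert average_precision(preds, truths, 0.5).ap == pytest.approx(1.0)

    def test_fp_then_tp_single_truth(self):
        truths = [boxed_truth(0)]
        preds = pattern_preds(truths, [False, True], confs=[0.9, 0.8])
        curve = average_precision(preds, truths, 0.5)
        assert curve.ap == pytest.approx(0.5)
        assert curve.recall[-1] == pytest.approx(1.0)

    def test_recall_nondecreasing_and_thresholds_sorted(self):
        truths = [boxed_truth(i) for i in range(3)]
        preds = pattern_preds(truths, [True, False, True, False, True])
        curve = average_precision(preds, truths, 0.5)
        assert list(curve.recall) == sorted(curve.recall)
        assert list(curve.thresholds) == sorted(curve.thresholds, reverse=True)
        assert 0.0 <= curve.ap <= 1.0

    @pytest.mark.parametrize("n_preds", [1, 2, 3, 4, 5, 6])
    def test_exhaustive_patterns_match_grid_oracle(self, n_preds):
        for flags in itertools.product([False, True], repeat=n_preds):
            n_tp = sum(flags)
            n_truth = max(n_tp, 1) + 1  # ensure recall < 1 reachable
            truths = [boxed_truth(i) for i in range(n_truth)]
            preds = pattern_preds(truths, flags)
            ap = average_precision(preds, truths, 0.5).ap
            assert ap == pytest.approx(ap_grid_oracle(flags, n_truth), abs=1e-3)

    def test_ten_prediction_patterns_sampled_exhaustively(self):
        rng = np.random.default_rng(17)
        patterns = rng.integers(0, 2, size=(40, 10)).astype(bool)
        for flags in patterns:
            n_truth = max(int(flags.sum()), 1)
            truths = [boxed_truth(i) for i in range(n_truth)]
            preds = pattern_preds(truths, list(flags))
            ap = average_precision(preds, truths, 0.5).ap
            assert ap == pytest.approx(ap_grid_oracle(flags, n_truth), abs=1e-3)

    def test_empty_truth_undefined(self):
        with pytest.raises(UndefinedMetricError):
            average_precision([], [], 0.5)


class TestMapOverThresholds:
    def test_perfect_detector(self):
        truths = [boxed_truth(i) for i in range(4)]
        preds = [pred_for(t, 0.9) for t in truths]
        assert map_over_thresholds(preds, truths) == (100.0, 100.0)

    def test_jittered_boxes_pass_50_fail_higher(self):
        truths = [boxed_truth(i) for i in range(4)]
        # offset 10 px on a 50-px box: IoU = 40/60 = 0.667 -> TP at 0.5/0.6/0.65, FP above
        preds = [pred_for(t, 0.9, iou_offset=10.0) for t in truths]
        map50, map50_95 = map_over_thresholds(preds, truths)
        assert map50 == 100.0
        assert map50_95 == pytest.approx(100.0 * 4 / 10)

    def test_ap_non_increasing_in_threshold(self):
        truths = [boxed_truth(i) for i in range(5)]
        rng = np.random.default_rng(23)
        preds = [pred_for(t, float(c), iou_offset=float(o)) for t, c, o in
                 zip(truths, rng.uniform(0.5, 1.0, 5), rng.uniform(0, 30, 5))]
        aps = [average_precision(preds, truths, t).ap for t in MAP_50_95_GRID]
        assert all(a >= b - 1e-12 for a, b in zip(aps, aps[1:]))

    def test_grid_is_ten_thresholds(self):
        assert len(MAP_50_95_GRID) == 10
        assert MAP_50_95_GRID[0] == 0.5 and MAP_50_95_GRID[-1] == 0.95


class TestKeypointOKSReport:
    def test_perfect_predictions(self, keypoints):
        pairs = [(keypoints, keypoints, 400.0)] * 5
        r = keypoint_oks_report(pairs)
        assert all(v == 1.0 for v in r.per_keypoint_mean.values())
        assert all(v == 0.0 for v in r.per_keypoint_std.values())
        assert r.overall_mean == 1.0
        assert r.n_excluded == 0

    def test_published_table_means_as_singletons(self, keypoints):
        # one pair whose six per-keypoint terms equal the published means;
        # their unweighted average reproduces the printed overall mean
        means = {
            "front_side": 0.932,
            "behind_side": 0.937,
            "left_eye": 0.896,
            "right_eye": 0.912,
            "left_side": 0.883,
            "right_side": 0.919,
        }
        area, k = 2500.0, 0.1
        s = math.sqrt(area)
        coords = {}
        for name in KEYPOINT_NAMES:
            t = keypoints[name]
            d = s * k * math.sqrt(-2.0 * math.log(means[name]))
            coords[name] = (t.x + d, t.y)
        pred = make_keypoints(coords=coords)
        r = keypoint_oks_report([(pred, keypoints, area)])
        for name, m in means.items():
            assert r.per_keypoint_mean[name] == pytest.approx(m, abs=1e-12)
        assert r.overall_mean == pytest.approx(sum(means.values()) / 6.0, abs=1e-12)
        assert r.overall_mean * 100 == pytest.approx(91.32, abs=0.005)

    def test_exclusion_counts_subthreshold_terms(self, keypoints):
        # left_eye term driven to ~0, everything else exact
        bad = make_keypoints(coords={"left_eye": (keypoints["left_eye"].x + 500.0, 0.0)})
        r = keypoint_oks_report([(bad, keypoints, 400.0), (keypoints, keypoints, 400.0)])
        assert r.n_excluded == 1
        assert r.per_keypoint_mean["left_eye"] == 1.0  # only the clean term survives

    def test_zero_threshold_keeps_everything(self, keypoints):
        bad = make_keypoints(coords={"left_eye": (keypoints["left_eye"].x + 500.0, 0.0)})
        r = keypoint_oks_report([(bad, keypoints, 400.0)], exclusion_threshold=0.0)
        assert r.n_excluded == 0
        assert r.per_keypoint_mean["left_eye"] == pytest.approx(0.0, abs=1e-6)

    def test_gaussian_noise_matches_closed_form_expectation(self, keypoints):
        # d^2 = dx^2 + dy^2 with iid N(0, sigma^2) components gives
        # E[exp(-d^2/(2 s^2 k^2))] = 1 / (1 + sigma^2/(s^2 k^2))
        rng = np.random.default_rng(29)
        area, k = 1600.0, 0.1
        s2k2 = area * k * k
        sigma = math.sqrt(s2k2)  # expectation = 0.5
        n = 10_000
        terms = []
        t = keypoints["front_side"]
        for dx, dy in rng.normal(0.0, sigma, size=(n, 2)):
            pred = keypoints.with_replaced(
                front_side=t.__class__("front_side", t.x + dx, t.y + dy)
            )
            r = keypoint_oks_report([(pred, keypoints, area)], exclusion_threshold=0.0)
            terms.append(r.per_keypoint_mean["front_side"])
        expected = 1.0 / (1.0 + sigma**2 / s2k2)
        se = np.std(terms, ddof=1) / math.sqrt(n)
        assert abs(np.mean(terms) - expected) < 3 * se

    def test_sample_std_over_images(self, keypoints):
        area, k = 2500.0, 0.1
        s = math.sqrt(area)
        terms = [0.9, 0.8, 0.7]
        pairs = []
        for term in terms:
            d = s * k * math.sqrt(-2.0 * math.log(term))
            t = keypoints["left_side"]
            pred = keypoints.with_replaced(
                left_side=t.__class__("left_side", t.x + d, t.y)
            )
            pairs.append((pred, keypoints, area))
        r = keypoint_oks_report(pairs)
        assert r.per_keypoint_std["left_side"] == pytest.approx(np.std(terms, ddof=1), abs=1e-9)

    def test_text_report_layout(self, keypoints):
        r = keypoint_oks_report([(keypoints, keypoints, 400.0)])
        text = report_to_text(r)
        for name in KEYPOINT_NAMES:
            assert name in text
        assert "Overall mean OKS" in text

    def test_empty_pairs_rejected(self):
        with pytest.raises(InvalidInputError):
            keypoint_oks_report([])
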