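"""Box geometry (IoU/CIoU) and detection metrics (P/R, AP, mAP)."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drowsekit import (
    Box,
    Detection,
    average_precision,
    ciou,
    evaluate_detections,
    iou,
    match_detections,
    mean_average_precision,
    pr_curve,
    precision_recall,
    recognition_rate,
)
from drowsekit.boxeval import PrCurve


def random_box(rng):
    x0, y0 = rng.uniform(-50, 50, 2)
    w, h = rng.uniform(0.5, 40, 2)
    return Box(x0, y0, x0 + w, y0 + h)


class TestCiou:
    def test_identical_boxes_perfect_match(self):
        b = Box(3, 4, 10, 12)
        out = ciou(b, b)
        assert out.iou == 1.0
        assert out.v == 0.0 and out.alpha == 0.0
        assert out.ciou == 1.0
        assert out.l_ciou == 0.0

    def test_offset_squares_hand_values(self):
        out = ciou(Box(0, 0, 2, 2), Box(1, 1, 3, 3))
        assert out.iou == pytest.approx(1 / 7)
        assert out.rho2 == pytest.approx(2.0)
        assert out.c2 == pytest.approx(18.0)
        assert out.v == 0.0
        assert out.ciou == pytest.approx(1 / 7 - 1 / 9)
        assert out.l_ciou == pytest.approx(1 - 1 / 7 + 1 / 9)

    def test_aspect_term_hand_value(self):
        # gt 2:1 vs pred 1:1, any placement
        expected = (4 / math.pi**2) * (math.atan(2) - math.atan(1)) ** 2
        out = ciou(Box(5, 5, 9, 9), Box(0, 0, 4, 2))
        assert out.v == pytest.approx(expected, abs=1e-9)
        assert out.v == pytest.approx(0.041956, abs=1e-6)

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            Box(0, 0, 0, 5)

    def test_swap_symmetry(self):
        # The aspect term squares the arctan difference, so although the
        # formula names gt and pred, every term — and hence CIoU — is
        # invariant under argument swap.
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b = random_box(rng), random_box(rng)
            ab, ba = ciou(a, b), ciou(b, a)
            assert ab.iou == pytest.approx(ba.iou)
            assert ab.rho2 == pytest.approx(ba.rho2)
            assert ab.c2 == pytest.approx(ba.c2)
            assert ab.v == pytest.approx(ba.v)
            assert ab.ciou == pytest.approx(ba.ciou)

    def test_bounds_randomized(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            out = ciou(random_box(rng), random_box(rng))
            # rho^2/c^2 < 1 and alpha*v < 1, so CIoU > -2; boxes far
            # apart with unlike aspect ratios do dip below -1.
            assert -2.0 < out.ciou <= 1.0
            assert 0.0 <= out.l_ciou < 3.0
            assert 0.0 <= out.iou <= 1.0
            assert out.v >= 0.0
            assert out.l_ciou == pytest.approx(
                1 - out.iou + out.rho2 / out.c2 + out.alpha * out.v
            )

    def test_loss_vanishes_along_homotopy(self):
        # Morph pred linearly onto gt: L_CIoU decreases to 0.
        gt = Box(10, 10, 30, 25)
        start = Box(0, 0, 8, 18)
        losses = []
        for t in np.linspace(0, 1, 21):
            pred = Box(
                start.x_min + t * (gt.x_min - start.x_min),
                start.y_min + t * (gt.y_min - start.y_min),
                start.x_max + t * (gt.x_max - start.x_max),
                start.y_max + t * (gt.y_max - start.y_max),
            )
            losses.append(ciou(pred, gt).l_ciou)
        assert losses[-1] == pytest.approx(0.0, abs=1e-12)
        assert all(b <= a + 1e-9 for a, b in zip(losses, losses[1:]))


class TestMatching:
    def test_exact_duplicates_all_tp(self):
        gts = [Box(0, 0, 10, 10), Box(20, 20, 30, 30)]
        dets = [Detection("face", b, 0.9) for b in gts]
        is_tp, gt_matched = match_detections(dets, gts)
        assert all(is_tp) and all(gt_matched)

    def test_confidence_ordered_enumeration(self):
        gt1, gt2 = Box(0, 0, 10, 10), Box(50, 50, 60, 60)
        dets = [
            Detection("face", Box(0, 0, 10, 10), 0.9),     # hits gt1
            Detection("face", Box(100, 100, 110, 110), 0.8),  # hits nothing
            Detection("face", Box(50, 50, 60, 60), 0.7),   # hits gt2
        ]
        is_tp, gt_matched = match_detections(dets, [gt1, gt2])
        assert is_tp == [True, False, True]
        assert all(gt_matched)

    def test_low_iou_is_fp_and_fn(self):
        gt = Box(0, 0, 10, 10)
        det = Detection("face", Box(6, 0, 16, 10), 0.9)  # IoU = 4/16 = 0.25
        is_tp, gt_matched = match_detections([det], [gt], iou_threshold=0.5)
        assert is_tp == [False] and gt_matched == [False]

    def test_gt_matched_at_most_once(self):
        gt = Box(0, 0, 10, 10)
        dets = [Detection("face", gt, 0.9), Detection("face", gt, 0.8)]
        is_tp, _ = match_detections(dets, [gt])
        assert is_tp == [True, False]

    def test_higher_confidence_claims_best_gt_first(self):
        gt = Box(0, 0, 10, 10)
        near = Detection("face", Box(1, 0, 11, 10), 0.5)
        exact = Detection("face", gt, 0.9)
        is_tp, _ = match_detections([near, exact], [gt])
        assert is_tp == [False, True]


class TestPrecisionRecall:
    def test_published_count_arithmetic(self):
        # 28,870 instances, 28,690 found: recall just under 0.994
        p, r = precision_recall(tp=28_690, fp=0, fn=180)
        assert r == pytest.approx(28_690 / 28_870)
        assert math.floor(r * 1000) / 1000 == 0.993

    def test_no_true_positives(self):
        p, r = precision_recall(tp=0, fp=5, fn=2)
        assert p == 0.0 and r == 0.0

    def test_zero_denominator_warns(self):
        with pytest.warns(UserWarning, match="precision"):
            p, _ = precision_recall(tp=0, fp=0, fn=2)
        assert p == 0.0

    def test_perfect(self):
        p, r = precision_recall(tp=10, fp=0, fn=0)
        assert p == 1.0 and r == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            precision_recall(-1, 0, 0)

    def test_recognition_rate(self):
        assert recognition_rate(49_850, 50_000) == pytest.approx(0.997)
        with pytest.raises(ValueError):
            recognition_rate(5, 0)
        with pytest.raises(ValueError):
            recognition_rate(6, 5)


class TestAveragePrecision:
    def test_perfect_detector(self):
        gts = [Box(i * 20, 0, i * 20 + 10, 10) for i in range(4)]
        dets = [Detection("face", b, 0.9 - 0.1 * i) for i, b in enumerate(gts)]
        curve = pr_curve(dets, gts)
        assert average_precision(curve) == pytest.approx(1.0)
        per_class, m_ap = evaluate_detections(dets, [("face", b) for b in gts],
                                              classes=("face",))
        assert m_ap == pytest.approx(1.0)

    def test_hand_interpolated_sweep(self):
        # points (R=0.5,P=1), (R=0.5,P=0.5), (R=1,P=2/3)
        curve = PrCurve(recall=(0.5, 0.5, 1.0), precision=(1.0, 0.5, 2 / 3),
                        tp=2, fp=1, fn=0, n_gt=2)
        assert average_precision(curve) == pytest.approx(0.5 + 0.5 * 2 / 3)

    def test_map_arithmetic(self):
        assert mean_average_precision(
            {"a": 1, "b": 1, "c": 1, "d": 1, "e": 0}
        ) == pytest.approx(0.8)

    def test_empty_curve_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            assert average_precision(
                PrCurve((), (), 0, 0, 0, 0)
            ) == 0.0

    def test_class_without_gt_excluded(self):
        with pytest.warns(UserWarning, match="excluded"):
            m = mean_average_precision({"a": 1.0, "b": math.nan})
        assert m == 1.0

    def test_oracle_small_detection_sets(self):
        """AP matches exhaustive cutoff enumeration for <= 5 detections."""
        rng = np.random.default_rng(3)
        for _ in range(40):
            n_gt = int(rng.integers(1, 4))
            gts = [Box(i * 30, 0, i * 30 + 10, 10) for i in range(n_gt)]
            n_det = int(rng.integers(1, 6))
            dets = []
            for _ in range(n_det):
                if rng.random() < 0.6:
                    target = gts[rng.integers(0, n_gt)]
                    jit = rng.uniform(-2, 2, 2)
                    box = Box(target.x_min + jit[0], target.y_min + jit[1],
                              target.x_max + jit[0], target.y_max + jit[1])
                else:
                    x = rng.uniform(200, 300)
                    box = Box(x, 50, x + 10, 60)
                dets.append(Detection("face", box, float(rng.random())))
            curve = pr_curve(dets, gts)
            ap = average_precision(curve)

            # Oracle: enumerate every confidence cutoff, take the PR point
            # at each, and integrate max-precision-at-recall>=r on a grid.
            is_tp, _ = match_detections(dets, gts)
            cutoffs = sorted({d.confidence for d in dets}, reverse=True)
            points = []
            for c in cutoffs:
                keep = [i for i, d in enumerate(dets) if d.confidence >= c]
                tp = sum(is_tp[i] for i in keep)
                fp = len(keep) - tp
                points.append((tp / n_gt, tp / (tp + fp)))
            grid = np.linspace(0, 1, 20001)[1:]
            p_of_r = np.zeros_like(grid)
            for r, p in points:
                p_of_r[grid <= r + 1e-12] = np.maximum(
                    p_of_r[grid <= r + 1e-12], p
                )
            oracle = float(np.mean(p_of_r))
            assert ap == pytest.approx(oracle, abs=5e-4)
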