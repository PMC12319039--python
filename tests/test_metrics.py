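"""Detection metrics (IoU, TP/FP assignment, AP) and count metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from podmatch.detections import BoundingBox, Detection, PodSet
from podmatch.metrics import (acc, acc_mean, assign_tp_fp, count_metrics,
                              evaluate_counts, evaluate_detections,
                              interpolated_ap, iou, mean_ap, pearson_r, pr_ap)


def pixel_set_iou(a: BoundingBox, b: BoundingBox, grid=20) -> float:
    """Brute-force oracle: rasterize both boxes and count pixels."""
    ga = np.zeros((grid, grid), dtype=bool)
    gb = np.zeros((grid, grid), dtype=bool)
    ga[int(a.y_min):int(a.y_max), int(a.x_min):int(a.x_max)] = True
    gb[int(b.y_min):int(b.y_max), int(b.x_min):int(b.x_max)] = True
    union = (ga | gb).sum()
    return (ga & gb).sum() / union if union else 0.0


def brute_force_ap(labels, n_truth) -> float:
    """Direct rectangular sum over rank positions."""
    ap, tp, prev_recall = 0.0, 0, 0.0
    for k, lab in enumerate(labels, start=1):
        tp += bool(lab)
        precision = tp / k
        recall = tp / n_truth if n_truth else 0.0
        ap += precision * (recall - prev_recall)
        prev_recall = recall
    return ap


class TestIoU:
    def test_identical_boxes(self):
        b = BoundingBox(3, 4, 10, 12)
        assert iou(b, b) == 1.0

    def test_disjoint_boxes(self):
        assert iou(BoundingBox(0, 0, 5, 5), BoundingBox(10, 10, 15, 15)) == 0.0

    def test_half_overlap_hand_value(self):
        assert iou(BoundingBox(0, 0, 10, 10), BoundingBox(5, 0, 15, 10)) \
            == pytest.approx(50 / 150)

    def test_symmetry_and_bounds(self, rng):
        for _ in range(50):
            x1, y1, x2, y2 = rng.integers(0, 19, 4)
            a = BoundingBox(x1, y1, x1 + rng.integers(1, 20 - x1), y1 + rng.integers(1, 20 - y1))
            x1, y1 = rng.integers(0, 19, 2)
            b = BoundingBox(x1, y1, x1 + rng.integers(1, 20 - x1), y1 + rng.integers(1, 20 - y1))
            v = iou(a, b)
            assert v == iou(b, a)
            assert 0.0 <= v <= 1.0
            assert (v == 1.0) == (a == b)

    @settings(deadline=None, max_examples=300, derandomize=True)
    @given(st.tuples(*[st.integers(0, 19) for _ in range(4)]),
           st.tuples(*[st.integers(0, 19) for _ in range(4)]))
    def test_matches_pixel_set_oracle(self, ca, cb):
        def mk(c):
            x1, y1, dx, dy = c
            return BoundingBox(x1, y1, min(x1 + dx + 1, 20), min(y1 + dy + 1, 20))
        a, b = mk(ca), mk(cb)
        assert iou(a, b) == pytest.approx(pixel_set_iou(a, b), abs=1e-12)


def _pod(box, cls=1, conf=1.0, view="front"):
    return Detection(box, cls, conf, view)


class TestAssignTpFp:
    def test_exact_hit(self):
        dets = [_pod(BoundingBox(0, 0, 10, 10))]
        truths = [_pod(BoundingBox(0, 0, 10, 10))]
        assert assign_tp_fp(dets, truths) == [True]

    def test_duplicate_detection_suppressed(self):
        box = BoundingBox(0, 0, 10, 10)
        dets = [_pod(box, conf=0.9), _pod(BoundingBox(1, 0, 11, 10), conf=0.8)]
        labels = assign_tp_fp(dets, [_pod(box)])
        assert labels == [True, False]

    def test_half_open_threshold_at_exactly_half(self):
        # IoU 0.5 exactly -> TP ("0.5 or higher"); just below -> FP
        dets_at = [_pod(BoundingBox(0, 0, 10, 5))]
        truths = [_pod(BoundingBox(0, 0, 10, 10))]
        assert assign_tp_fp(dets_at, truths) == [True]
        dets_below = [_pod(BoundingBox(0, 0, 10, 4))]
        assert assign_tp_fp(dets_below, truths) == [False]

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(0, 6), st.integers(0, 6), st.integers(0, 9999))
    def test_conservation(self, nd, nt, seed):
        rng = np.random.default_rng(seed)
        def boxes(n):
            out = []
            for _ in range(n):
                x, y = rng.integers(0, 30, 2)
                out.append(_pod(BoundingBox(x, y, x + rng.integers(2, 10),
                                            y + rng.integers(2, 10)),
                                conf=float(rng.random())))
            return out
        dets, truths = boxes(nd), boxes(nt)
        labels = assign_tp_fp(dets, truths)
        tp = sum(labels)
        assert tp + (nd - tp) == nd          # TP + FP = detections
        assert tp <= nt                       # each truth claimed at most once


class TestAveragePrecision:
    def test_single_true_positive(self):
        _, _, ap = pr_ap([True], 1)
        assert ap == 1.0

    def test_fp_then_tp_halves_ap(self):
        _, _, ap = pr_ap([False, True], 1)
        assert ap == 0.5

    def test_all_false_positives(self):
        _, _, ap = pr_ap([False, False, False], 2)
        assert ap == 0.0

    def test_no_truth_gives_zero(self):
        assert pr_ap([True, False], 0)[2] == 0.0

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.lists(st.booleans(), max_size=10), st.integers(0, 12))
    def test_matches_brute_force(self, labels, extra_truth):
        n_truth = sum(labels) + extra_truth
        _, _, ap = pr_ap(labels, n_truth)
        assert ap == pytest.approx(brute_force_ap(labels, n_truth), abs=1e-12)

    def test_interpolated_ap_upper_bounds_raw(self):
        labels = [False, True, True, False, True]
        _, _, raw = pr_ap(labels, 4)
        assert interpolated_ap(labels, 4) >= raw

    def test_mean_ap(self):
        assert mean_ap([1, 1, 1, 1]) == 1.0
        assert mean_ap([0.2, 0.4, 0.6, 0.8]) == pytest.approx(0.5)
        assert mean_ap([0.73]) == pytest.approx(0.73)


class TestEvaluateDetections:
    def test_perfect_oracle_detections(self, small_scene):
        from podmatch.synth import truth_to_detections
        _, _, _, truth = small_scene
        dets = truth_to_detections(truth, "front")
        report = evaluate_detections(dets, dets)
        for cls, m in report.per_class.items():
            if m["tp"] + m["fn"] > 0:
                assert m["precision"] == 1.0 and m["recall"] == 1.0
        assert report.map == pytest.approx(
            np.mean([m["ap"] for m in report.per_class.values()]))

    def test_tp_plus_fn_equals_truth_count(self, small_scene):
        from podmatch.synth import truth_to_detections
        _, _, _, truth = small_scene
        dets = truth_to_detections(truth, "front")
        shifted = PodSet("p", "front", [
            Detection(BoundingBox(d.box.x_min + 3, d.box.y_min, d.box.x_max + 3,
                                  d.box.y_max), d.pod_class, 0.8, "front")
            for d in dets])
        report = evaluate_detections(shifted, dets)
        for cls, m in report.per_class.items():
            n_truth = sum(1 for d in dets if d.pod_class == cls)
            assert m["tp"] + m["fn"] == n_truth


class TestCountMetrics:
    def test_perfect_prediction(self):
        mae, rmse, r = count_metrics([3, 7, 9], [3, 7, 9])
        assert (mae, rmse, r) == (0.0, 0.0, 1.0)

    def test_hand_computed_example(self):
        mae, rmse, r = count_metrics((10, 20), (12, 18))
        assert mae == 2.0
        assert rmse == 2.0
        assert r == pytest.approx(1 - 8 / 50)

    def test_constant_truth_undefined_r(self):
        with pytest.raises(ValueError):
            count_metrics([5, 5], [4, 6])

    def test_rmse_permutation_invariant(self, rng):
        t = rng.integers(1, 50, 12).astype(float)
        c = t + rng.normal(0, 3, 12)
        perm = rng.permutation(12)
        m1 = count_metrics(t, c)
        m2 = count_metrics(t[perm], c[perm])
        assert m1 == pytest.approx(m2)

    def test_r_can_be_negative(self):
        _, _, r = count_metrics([1, 2, 3], [30, -10, 25])
        assert r < 0

    def test_pearson_differs_from_determination_form(self):
        t, c = [10.0, 20.0, 30.0], [22.0, 32.0, 42.0]
        assert pearson_r(t, c) == pytest.approx(1.0)       # perfect linear
        _, _, r = count_metrics(t, c)
        assert r < 1.0                                      # penalizes offset


class TestAcc:
    def test_exact_prediction(self):
        assert acc(10, 10) == 1.0

    def test_undercount(self):
        assert acc(10, 8) == pytest.approx(0.8)

    def test_negative_branch_unclamped(self):
        assert acc(10, 21) == pytest.approx(-0.1)

    def test_zero_truth_undefined(self):
        with pytest.raises(ValueError):
            acc(0, 3)

    def test_acc_mean_arity_and_value(self):
        assert acc_mean([1, 1, 1, 1, 0]) == pytest.approx(0.8)
        assert acc_mean([0.3] * 5) == pytest.approx(0.3)
        assert acc_mean([1, 0, 1, 0, 1]) == acc_mean([0, 1, 1, 1, 0])
        with pytest.raises(ValueError):
            acc_mean([1, 1, 1, 1])


class TestEvaluateCounts:
    def test_report_on_small_table(self):
        import pandas as pd
        truth = pd.DataFrame({"plant_id": ["a", "b"], "one": [10, 20], "two": [5, 6],
                              "three": [8, 9], "four": [1, 2], "total": [24, 37]})
        pred = truth.copy()
        pred["one"] = [12, 18]
        report = evaluate_counts(truth, pred)
        assert report.per_category["one"]["mae"] == 2.0
        assert report.per_category["one"]["r"] == pytest.approx(0.84)
        assert report.per_category["total"]["rmse"] == 0.0

    def test_mismatched_plants_rejected(self):
        import pandas as pd
        truth = pd.DataFrame({"plant_id": ["a"], "one": [1], "two": [1],
                              "three": [1], "four": [1], "total": [4]})
        pred = truth.copy()
        pred["plant_id"] = ["b"]
        with pytest.raises(ValueError):
            evaluate_counts(truth, pred)
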