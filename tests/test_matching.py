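"""Greedy cross-view matching, deduplicated counting, and plant fusion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from podmatch.detections import BoundingBox, Detection, PodSet, flip_boxes
from podmatch.matching import (MatchConfig, MatchResult, count_from_match,
                               fuse_plant, greedy_match, oracle_scorer)
from podmatch.synth import SynthConfig, generate_scene, truth_to_detections


def reference_greedy(sim, threshold, order, n_rear):
    """Independent list-based trace of the sequential correction loop:
    visit frontal pods in the given order, take the most similar remaining
    rear pod, pair when strictly above threshold, else record front-only."""
    remaining = list(range(n_rear))
    pairs, front_only = [], []
    for i in order:
        best_j = None
        best = -1.0
        for j in remaining:
            if sim[i][j] > best:
                best, best_j = sim[i][j], j
        if best_j is not None and best > threshold:
            pairs.append((i, best_j))
            remaining.remove(best_j)
        else:
            front_only.append(i)
    return pairs, front_only, remaining


class TestGreedyMatch:
    def test_empty_matrix(self):
        res = greedy_match(np.zeros((0, 0)))
        assert res.pairs == [] and res.front_only == [] and res.rear_only == []

    def test_threshold_is_strict(self):
        res = greedy_match(np.array([[0.5]]))
        assert res.pairs == []
        assert res.front_only == [0] and res.rear_only == [0]
        res2 = greedy_match(np.array([[0.5000001]]))
        assert len(res2.pairs) == 1

    def test_hand_traced_two_by_two(self):
        sim = np.array([[0.9, 0.2], [0.4, 0.3]])
        res = greedy_match(sim, MatchConfig(row_order="index"))
        assert res.pairs == [(0, 0, 0.9)]
        assert res.front_only == [1]
        assert res.rear_only == [1]
        assert res.n_pods == 3

    def test_argmax_ties_break_to_lowest_rear_index(self):
        sim = np.array([[0.8, 0.8]])
        res = greedy_match(sim)
        assert res.pairs == [(0, 0, 0.8)]

    def test_confidence_order_changes_result(self):
        # both rows prefer column 0; the higher-confidence row wins it
        sim = np.array([[0.9, 0.0], [0.95, 0.6]])
        res = greedy_match(sim, MatchConfig(row_order="confidence_desc"),
                           row_priority=[0.5, 0.99])
        assert (1, 0, 0.95) in res.pairs
        assert (0, 1, 0.0) not in res.pairs  # row 0 falls below threshold
        assert res.front_only == [0]

    def test_non_finite_entries_rejected(self):
        with pytest.raises(ValueError):
            greedy_match(np.array([[np.nan]]))

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.integers(0, 6), st.integers(0, 6), st.integers(0, 10_000))
    def test_matches_reference_trace(self, nf, nr, seed):
        rng = np.random.default_rng(seed)
        sim = np.round(rng.random((nf, nr)), 3)
        res = greedy_match(sim, MatchConfig(row_order="index"))
        ref_pairs, ref_front, ref_rear = reference_greedy(
            sim.tolist(), 0.5, list(range(nf)), nr)
        assert [(i, j) for i, j, _ in res.pairs] == ref_pairs
        assert res.front_only == ref_front
        assert res.rear_only == ref_rear

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(0, 8), st.integers(0, 8), st.integers(0, 10_000),
           st.floats(0.0, 1.0))
    def test_partition_invariant(self, nf, nr, seed, threshold):
        sim = np.random.default_rng(seed).random((nf, nr))
        res = greedy_match(sim, MatchConfig(threshold=threshold))
        assert len(res.pairs) + len(res.front_only) == nf
        assert len(res.pairs) + len(res.rear_only) == nr
        front_seen = sorted([i for i, _, _ in res.pairs] + res.front_only)
        rear_seen = sorted([j for _, j, _ in res.pairs] + res.rear_only)
        assert front_seen == list(range(nf)) and rear_seen == list(range(nr))
        assert all(s > threshold for _, _, s in res.pairs)

    def test_count_bounds_at_threshold_extremes(self):
        rng = np.random.default_rng(3)
        sim = rng.random((4, 6))
        # threshold 1.0: nothing strictly exceeds it -> every det is its own pod
        res_hi = greedy_match(sim, MatchConfig(threshold=1.0))
        assert res_hi.n_pods == 4 + 6
        # all-ones matrix below threshold 1: maximal pairing
        res_lo = greedy_match(np.ones((4, 6)), MatchConfig(threshold=0.5))
        assert res_lo.n_pods == max(4, 6)

    def test_total_monotone_in_threshold(self):
        sim = np.random.default_rng(11).random((5, 5))
        totals = [greedy_match(sim, MatchConfig(threshold=t)).n_pods
                  for t in np.linspace(0, 1, 21)]
        assert totals == sorted(totals)


def _det(cls, conf=1.0, view="front", x=0):
    return Detection(BoundingBox(x, 0, x + 10, 10), cls, conf, view)


class TestCountFromMatch:
    def test_empty_input_gives_zero_counts(self):
        count = count_from_match(MatchResult(), PodSet("p", "front"), PodSet("p", "rear"))
        assert count.as_dict() == {1: 0, 2: 0, 3: 0, 4: 0, "total": 0}

    def test_pairs_and_survivors_each_count_once(self):
        front = PodSet("p", "front", [_det(3), _det(1, x=20)])
        rear = PodSet("p", "rear", [_det(3, view="rear"), _det(2, view="rear", x=20)])
        result = MatchResult(pairs=[(0, 0, 0.9)], front_only=[1], rear_only=[1])
        count = count_from_match(result, front, rear)
        assert count.as_dict() == {1: 1, 2: 1, 3: 1, 4: 0, "total": 3}

    def test_class_conflict_resolved_by_confidence(self):
        front = PodSet("p", "front", [_det(2, conf=0.9)])
        rear = PodSet("p", "rear", [_det(3, conf=0.4, view="rear")])
        result = MatchResult(pairs=[(0, 0, 0.8)])
        count = count_from_match(result, front, rear,
                                 MatchConfig(class_conflict="higher_confidence"))
        assert count.counts[2] == 1 and count.counts[3] == 0
        count_f = count_from_match(result, front, rear,
                                   MatchConfig(class_conflict="frontal"))
        assert count_f.counts[2] == 1

    def test_conflict_frontal_fallback_differs_from_confidence(self):
        front = PodSet("p", "front", [_det(2, conf=0.3)])
        rear = PodSet("p", "rear", [_det(3, conf=0.9, view="rear")])
        result = MatchResult(pairs=[(0, 0, 0.8)])
        by_conf = count_from_match(result, front, rear,
                                   MatchConfig(class_conflict="higher_confidence"))
        assert by_conf.counts[3] == 1
        frontal = count_from_match(result, front, rear,
                                   MatchConfig(class_conflict="frontal"))
        assert frontal.counts[2] == 1


class TestFusePlant:
    def _aligned_sets(self, truth):
        front = truth_to_detections(truth, "front")
        rear = flip_boxes(truth_to_detections(truth, "rear"), truth.image_size[0])
        return front, rear

    def test_empty_rear_reduces_to_front_histogram(self, small_scene):
        _, _, _, truth = small_scene
        front, _ = self._aligned_sets(truth)
        rear = PodSet(front.plant_id, "rear")
        result, count = fuse_plant(front, rear, oracle_scorer)
        assert len(result.pairs) == 0
        assert count.as_dict() == {**front.class_histogram(), "total": len(front)}

    def test_oracle_recovers_exact_truth_under_occlusion(self, small_scene):
        _, _, _, truth = small_scene
        front, rear = self._aligned_sets(truth)
        _, count = fuse_plant(front, rear, oracle_scorer)
        truth_counts = truth.true_counts
        assert count.as_dict() == {1: truth_counts[1], 2: truth_counts[2],
                                   3: truth_counts[3], 4: truth_counts[4],
                                   "total": truth_counts["total"]}

    def test_rear_only_pods_supplement_front_count(self):
        cfg = SynthConfig(n_pods_range=(20, 20), occlusion_rate=0.5, seed=77)
        _, _, truth = generate_scene(cfg)
        front = truth_to_detections(truth, "front")
        rear = flip_boxes(truth_to_detections(truth, "rear"), truth.image_size[0])
        result, count = fuse_plant(front, rear, oracle_scorer)
        hidden_from_front = sum(not p.visible_front for p in truth.pods)
        assert hidden_from_front > 0
        assert count.total == len(front) + len(result.rear_only)
        assert count.total - len(front) == hidden_from_front
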