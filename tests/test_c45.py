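"""C4.5 entropy arithmetic, segmentation points, and tree growth."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oculodx import c45
from oculodx.c45 import (SegmentationPoint, best_split, build_tree, classify,
                         entropy, enumerate_segmentation_points, gain_ratio,
                         partition, tree_points)


# --- independent literal transcription of the split arithmetic, used as
# --- the dual-implementation oracle (kept deliberately naive)
def oracle_gain_ratio(X, y, feat, thr, n_classes):
    def H(labels):
        n = len(labels)
        s = 0.0
        for l in range(1, n_classes + 1):
            nl = sum(1 for v in labels if v == l)
            if nl:
                s -= (nl / n) * math.log2(nl / n)
        return s

    left = [y[i] for i in range(len(y)) if X[i][feat - 1] <= thr]
    right = [y[i] for i in range(len(y)) if X[i][feat - 1] > thr]
    n = len(y)
    h_d = H(list(y))
    h_cond = len(left) / n * H(left) + len(right) / n * H(right)
    g = h_d - h_cond
    h_j = -(len(left) / n) * math.log2(len(left) / n) \
        - (len(right) / n) * math.log2(len(right) / n)
    return g / h_j


class TestEntropy:
    def test_pure_set_has_zero_entropy(self):
        assert entropy([5, 0, 0]) == 0.0

    def test_balanced_binary_is_one_bit(self):
        assert entropy([4, 4]) == pytest.approx(1.0)

    def test_group_composition_entropy(self):
        assert entropy([12, 8, 12]) == pytest.approx(1.5613, abs=5e-5)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            entropy([0, 0, 0])
        with pytest.raises(ValueError):
            entropy([-1, 2])

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.integers(0, 50), min_size=1, max_size=6))
    def test_entropy_bounds(self, counts):
        if sum(counts) == 0:
            return
        h = entropy(counts)
        w = len(counts)
        assert 0.0 <= h <= math.log2(w) + 1e-12
        assert (h == 0.0) == (sum(c > 0 for c in counts) == 1)


class TestPartition:
    def test_threshold_below_all_values(self):
        X = np.array([[1.0], [2.0], [3.0]])
        left, right = partition(X, SegmentationPoint(1, 0.5))
        assert left.sum() == 0 and right.sum() == 3

    def test_midpoint_splits_evenly(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        left, right = partition(X, SegmentationPoint(1, 2.5))
        assert left.sum() == 2 and right.sum() == 2

    def test_conservation_on_random_splits(self, rng):
        X = rng.random((30, 4))
        for _ in range(100):
            J = SegmentationPoint(int(rng.integers(1, 5)),
                                  float(rng.random()))
            left, right = partition(X, J)
            assert left.sum() + right.sum() == 30
            assert not np.any(left & right)


class TestGainRatio:
    def test_perfect_balanced_split_is_one(self):
        X = np.array([[0.1], [0.2], [0.8], [0.9]])
        y = np.array([1, 1, 2, 2])
        assert gain_ratio(X, y, SegmentationPoint(1, 0.5)) == pytest.approx(1.0)

    def test_pure_node_has_zero_gain(self):
        X = np.array([[0.1], [0.4], [0.9]])
        y = np.array([2, 2, 2])
        assert gain_ratio(X, y, SegmentationPoint(1, 0.5),
                          n_classes=3) == pytest.approx(0.0)

    def test_degenerate_split_rejected(self):
        X = np.array([[0.1], [0.2]])
        with pytest.raises(ValueError, match="degenerate"):
            gain_ratio(X, np.array([1, 2]), SegmentationPoint(1, 0.05))

    def test_matches_literal_transcription(self, rng):
        """Dual-implementation oracle on 20 random datasets, 1e-12."""
        for _ in range(20):
            n = int(rng.integers(4, 20))
            m = int(rng.integers(1, 4))
            X = rng.random((n, m))
            y = rng.integers(1, 4, size=n)
            feat = int(rng.integers(1, m + 1))
            vals = np.sort(X[:, feat - 1])
            thr = float((vals[n // 2 - 1] + vals[n // 2]) / 2)
            J = SegmentationPoint(feat, thr)
            try:
                ours = gain_ratio(X, y, J, n_classes=3)
            except ValueError:
                continue
            assert ours == pytest.approx(
                oracle_gain_ratio(X, y, feat, thr, 3), abs=1e-12)

    def test_gain_bounds(self, rng):
        """0 <= g(D,J) <= H(D) and H(D|J) <= H(D) on random data."""
        for _ in range(50):
            n = int(rng.integers(4, 25))
            X = rng.random((n, 2))
            y = rng.integers(1, 4, size=n)
            h_d = entropy(np.bincount(y, minlength=4)[1:])
            for J in enumerate_segmentation_points(X):
                if J.degenerate:
                    continue
                left, right = partition(X, J)
                if left.sum() == 0 or right.sum() == 0:
                    continue
                n1, n2 = left.sum(), right.sum()
                h_cond = (n1 / n) * entropy(np.bincount(y[left], minlength=4)[1:]) \
                    + (n2 / n) * entropy(np.bincount(y[right], minlength=4)[1:])
                assert h_cond <= h_d + 1e-12
                gr = gain_ratio(X, y, J, n_classes=3)
                assert gr >= -1e-12


class TestEnumerate:
    def test_nominal_count_for_study_configuration(self, rng):
        X = rng.random((32, 12))
        points = enumerate_segmentation_points(X)
        assert len(points) == 372

    def test_single_midpoint(self):
        points = enumerate_segmentation_points(np.array([[1.0], [3.0]]))
        assert len(points) == 1
        assert points[0].threshold == 2.0 and not points[0].degenerate

    def test_tied_values_yield_degenerate_points(self):
        points = enumerate_segmentation_points(np.array([[2.0], [2.0], [2.0]]))
        assert len(points) == 2
        assert all(p.degenerate for p in points)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            enumerate_segmentation_points(np.array([[1.0]]))


class TestBestSplit:
    def test_single_valid_candidate_returned(self):
        X = np.array([[0.0], [1.0]])
        y = np.array([1, 2])
        J = SegmentationPoint(1, 0.5)
        assert best_split(X, y, [J]) == J

    def test_matches_brute_force_argmax(self, rng):
        """Exhaustive-search oracle on random datasets with N <= 12, M <= 3."""
        for _ in range(30):
            n = int(rng.integers(4, 13))
            m = int(rng.integers(1, 4))
            X = np.round(rng.random((n, m)), 2)
            y = rng.integers(1, 4, size=n)
            if len(np.unique(y)) < 2:
                continue
            cands = enumerate_segmentation_points(X)
            chosen = best_split(X, y, cands, n_classes=3)
            scored = []
            for J in cands:
                if J.degenerate:
                    continue
                left, right = partition(X, J)
                if left.sum() == 0 or right.sum() == 0:
                    continue
                scored.append((oracle_gain_ratio(X, y, J.feature_index,
                                                 J.threshold, 3), J))
            if not scored:
                assert chosen is None
                continue
            best_gr = max(s for s, _ in scored)
            winners = sorted(J for s, J in scored if s == best_gr)
            assert chosen == winners[0]

    def test_tie_breaks_to_lowest_feature_index(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 0.0], [1.0, 1.0]])
        y = np.array([1, 2, 1, 2])
        chosen = best_split(X, y, enumerate_segmentation_points(X))
        assert chosen.feature_index == 1

    def test_no_valid_candidate_gives_none(self):
        X = np.array([[1.0], [1.0]])
        y = np.array([1, 2])
        assert best_split(X, y, enumerate_segmentation_points(X)) is None


class TestBuildTree:
    def toy(self):
        X = np.array([[0.1, 0.0], [0.2, 0.9], [0.15, 0.5],
                      [0.5, 0.1], [0.6, 0.2], [0.55, 0.3],
                      [0.9, 0.8], [0.85, 0.9], [0.95, 0.7]])
        y = np.array([1, 1, 1, 2, 2, 2, 3, 3, 3])
        return X, y

    def test_separable_data_reaches_training_purity(self):
        X, y = self.toy()
        tree = build_tree(X, y)
        assert all(classify(tree, x) == l for x, l in zip(X, y))

    def test_pure_input_is_single_leaf(self):
        X = np.array([[0.1], [0.9]])
        y = np.array([2, 2])
        marked = set()
        tree = build_tree(X, y, marked=marked, n_classes=3)
        assert tree.is_leaf and tree.label == 2 and not marked

    def test_marked_points_never_reused(self):
        X, y = self.toy()
        marked = set()
        tree = build_tree(X, y, marked=marked)
        used = tree_points(tree)
        assert len(used) == len(set(used))
        assert set(used) <= marked

    def test_limited_random_candidates_bound_tree_size(self, rng, default_result):
        """Randomly offering 8 of the 372 points per node cannot use more
        than 8 distinct points in the whole tree."""
        table = default_result.ef_tables[2]
        X = table[[f"f{i}" for i in range(1, 13)]].to_numpy()
        y = np.array([{"C1": 1, "C2": 2, "C3": 3}[l] for l in table["label"]])
        cands = enumerate_segmentation_points(X)

        def policy(pool):
            idx = rng.choice(len(pool), size=min(8, len(pool)), replace=False)
            return [pool[i] for i in idx]

        tree = build_tree(X, y, candidates=cands, candidate_policy=policy)
        assert len(set(tree_points(tree))) <= 8

    def test_empty_sample_set_rejected(self):
        with pytest.raises(ValueError):
            build_tree(np.empty((0, 2)), np.empty(0, dtype=int))

    def test_majority_leaf_tie_goes_to_lowest_class(self):
        X = np.array([[1.0], [1.0]])
        y = np.array([2, 1])
        tree = build_tree(X, y, n_classes=3)
        assert tree.is_leaf and tree.label == 1


class TestClassify:
    def test_single_leaf_tree(self):
        from oculodx.c45 import TreeNode
        leaf = TreeNode(label=3, n_samples=5)
        assert classify(leaf, np.zeros(12)) == 3

    def test_hand_built_depth_two_tree(self):
        from oculodx.c45 import TreeNode
        tree = TreeNode(
            point=SegmentationPoint(1, 0.5),
            left=TreeNode(point=SegmentationPoint(2, 0.3),
                          left=TreeNode(label=1), right=TreeNode(label=2)),
            right=TreeNode(label=3))
        assert classify(tree, [0.4, 0.1]) == 1
        assert classify(tree, [0.4, 0.9]) == 2
        assert classify(tree, [0.9, 0.0]) == 3

    def test_short_feature_vector_rejected(self):
        from oculodx.c45 import TreeNode
        tree = TreeNode(point=SegmentationPoint(3, 0.5),
                        left=TreeNode(label=1), right=TreeNode(label=2))
        with pytest.raises(ValueError):
            classify(tree, [0.1, 0.2])


def test_tree_json_and_dot_roundtrip(tmp_path, rng):
    X = rng.random((12, 3))
    y = rng.integers(1, 4, size=12)
    tree = build_tree(X, y, n_classes=3)
    c45.save_tree(tree, tmp_path / "tree.json")
    back = c45.load_tree(tmp_path / "tree.json")
    for x in rng.random((20, 3)):
        assert classify(tree, x) == classify(back, x)
    dot = c45.tree_to_dot(tree)
    assert dot.startswith("digraph") and "->" in dot
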