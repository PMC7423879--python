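"""C4.5 decision trees on continuous features via segmentation points.

A segmentation point J is a (feature, threshold) pair; with N samples each
of the M features offers N-1 candidate thresholds (midpoints between
consecutive order statistics), giving a nominal pool of M * (N-1) points.
Node branching picks the candidate maximizing the information gain rate:

    H(D)     = -sum_l (N_l / N) log2(N_l / N)          sample-set entropy
    H(D | J) = (J1/N) H(J1) + (J2/N) H(J2)             split-conditional
    g(D, J)  = H(D) - H(D | J)                         information gain
    H(J)     = -(J1/N) log2(J1/N) - (J2/N) log2(J2/N)  split entropy
    gr(D, J) = g(D, J) / H(J)                          gain rate

Trees grow unpruned to purity.  A per-tree *marked* set records every
segmentation point already used at an ancestor or preceding node so that
the random-forest stage never reuses a point within one tree.  All
tie-breaks are deterministic (lowest feature index, then lowest threshold;
leaf label ties go to the lowest class index).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np


@dataclass(frozen=True, order=True)
class SegmentationPoint:
    """A candidate binary split: feature index (1-based) and threshold."""

    feature_index: int
    threshold: float
    degenerate: bool = False  # threshold does not separate two values


@dataclass
class TreeNode:
    """Internal node (split + children) or leaf (label + sample count)."""

    point: SegmentationPoint | None = None
    left: "TreeNode | None" = None   # feature <= threshold
    right: "TreeNode | None" = None  # feature > threshold
    label: int | None = None
    n_samples: int = 0

    @property
    def is_leaf(self) -> bool:
        return self.point is None


def entropy(class_counts: Sequence[float]) -> float:
    """Shannon entropy in bits of a class-count vector (0 log 0 = 0)."""
    counts = np.asarray(class_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("class counts must be >= 0")
    n = counts.sum()
    if n == 0:
        raise ValueError("entropy of an empty sample set is undefined")
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _class_counts(y: np.ndarray, n_classes: int) -> np.ndarray:
    return np.bincount(y, minlength=n_classes + 1)[1:]


def partition(X: np.ndarray, J: SegmentationPoint) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks (left, right) splitting rows at feature <= threshold."""
    col = X[:, J.feature_index - 1]
    left = col <= J.threshold
    return left, ~left


def gain_ratio(X: np.ndarray, y: np.ndarray, J: SegmentationPoint,
               n_classes: int | None = None) -> float:
    """Information gain rate of split J; raises on a degenerate split."""
    n_classes = n_classes or int(y.max())
    left, right = partition(X, J)
    n1, n2 = int(left.sum()), int(right.sum())
    n = n1 + n2
    if n1 == 0 or n2 == 0:
        raise ValueError("degenerate segmentation point: one side is empty")
    h_d = entropy(_class_counts(y, n_classes))
    h_cond = (n1 / n) * entropy(_class_counts(y[left], n_classes)) \
        + (n2 / n) * entropy(_class_counts(y[right], n_classes))
    gain = h_d - h_cond
    h_split = entropy([n1, n2])
    return gain / h_split


def enumerate_segmentation_points(X: np.ndarray) -> list[SegmentationPoint]:
    """All M * (N-1) candidate points: per-feature order-statistic midpoints.

    Midpoints between tied consecutive values cannot separate anything and
    are retained but flagged degenerate, preserving the nominal count.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if n < 2:
        raise ValueError("need at least two samples to enumerate splits")
    points = []
    for j in range(m):
        vals = np.sort(X[:, j])
        for a, b in zip(vals[:-1], vals[1:]):
            points.append(SegmentationPoint(
                feature_index=j + 1, threshold=float((a + b) / 2.0),
                degenerate=bool(a == b)))
    return points


def best_split(X: np.ndarray, y: np.ndarray,
               candidates: Sequence[SegmentationPoint],
               n_classes: int | None = None) -> SegmentationPoint | None:
    """Candidate with the maximum gain rate, or None if none is valid.

    Candidates that are flagged degenerate, or whose split leaves one side
    empty on *these* samples, are skipped.  Ties break toward the lowest
    (feature_index, threshold).
    """
    best: SegmentationPoint | None = None
    best_gr = -np.inf
    for J in sorted(candidates):
        if J.degenerate:
            continue
        try:
            gr = gain_ratio(X, y, J, n_classes)
        except ValueError:
            continue
        if gr > best_gr:
            best, best_gr = J, gr
    return best


CandidatePolicy = Callable[[list[SegmentationPoint]], list[SegmentationPoint]]


def build_tree(
    X: np.ndarray,
    y: np.ndarray,
    candidates: Sequence[SegmentationPoint] | None = None,
    candidate_policy: CandidatePolicy | None = None,
    marked: set[SegmentationPoint] | None = None,
    n_classes: int | None = None,
) -> TreeNode:
    """Grow an unpruned C4.5 tree to purity.

    A node becomes a leaf when it is pure, all its feature vectors are
    identical, or no unmarked valid candidate remains (the leaf label is
    the majority class, ties to the lowest class index).  Otherwise the
    node branches on ``best_split`` over ``candidate_policy`` applied to
    the unmarked candidates; the chosen point is added to ``marked`` so no
    descendant or later node of the same tree reuses it.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(X) == 0:
        raise ValueError("cannot grow a tree from an empty sample set")
    if candidates is None:
        candidates = enumerate_segmentation_points(X)
    if marked is None:
        marked = set()
    n_classes = n_classes or int(y.max())
    return _grow(X, y, list(candidates), candidate_policy, marked, n_classes)


def _majority(y: np.ndarray) -> int:
    vals, counts = np.unique(y, return_counts=True)
    return int(vals[np.argmax(counts)])  # np.argmax ties -> first (lowest)


def _grow(X, y, candidates, policy, marked, n_classes) -> TreeNode:
    node = TreeNode(label=_majority(y), n_samples=len(y))
    if len(np.unique(y)) == 1:
        return node
    if np.all(X == X[0]):
        return node
    pool = [J for J in candidates if J not in marked]
    if policy is not None:
        pool = policy(pool)
    J = best_split(X, y, pool, n_classes)
    if J is None:
        return node
    marked.add(J)
    left, right = partition(X, J)
    node.point = J
    node.label = None
    node.left = _grow(X[left], y[left], candidates, policy, marked, n_classes)
    node.right = _grow(X[right], y[right], candidates, policy, marked, n_classes)
    return node


def classify(tree: TreeNode, features: np.ndarray,
             n_features: int | None = None) -> int:
    """Root-to-leaf descent by threshold comparisons."""
    x = np.asarray(features, dtype=float)
    if n_features is not None and len(x) != n_features:
        raise ValueError(f"expected {n_features} features, got {len(x)}")
    node = tree
    while not node.is_leaf:
        if len(x) < node.point.feature_index:
            raise ValueError("feature vector shorter than tree expects")
        if x[node.point.feature_index - 1] <= node.point.threshold:
            node = node.left
        else:
            node = node.right
    return node.label


def tree_points(tree: TreeNode) -> list[SegmentationPoint]:
    """All segmentation points used by a tree's internal nodes."""
    out = []
    stack = [tree]
    while stack:
        node = stack.pop()
        if not node.is_leaf:
            out.append(node.point)
            stack.extend([node.left, node.right])
    return out


def tree_depth(tree: TreeNode) -> int:
    if tree.is_leaf:
        return 0
    return 1 + max(tree_depth(tree.left), tree_depth(tree.right))


# ---- serialization -------------------------------------------------------

def tree_to_dict(tree: TreeNode) -> dict:
    if tree.is_leaf:
        return {"leaf": True, "label": tree.label, "n_samples": tree.n_samples}
    return {"leaf": False,
            "feature_index": tree.point.feature_index,
            "threshold": tree.point.threshold,
            "n_samples": tree.n_samples,
            "left": tree_to_dict(tree.left),
            "right": tree_to_dict(tree.right)}


def tree_from_dict(d: dict) -> TreeNode:
    if d["leaf"]:
        return TreeNode(label=d["label"], n_samples=d["n_samples"])
    return TreeNode(point=SegmentationPoint(d["feature_index"], d["threshold"]),
                    n_samples=d.get("n_samples", 0),
                    left=tree_from_dict(d["left"]),
                    right=tree_from_dict(d["right"]))


def save_tree(tree: TreeNode, path: str | Path) -> None:
    Path(path).write_text(json.dumps(tree_to_dict(tree), indent=1))


def load_tree(path: str | Path) -> TreeNode:
    return tree_from_dict(json.loads(Path(path).read_text()))


def tree_to_dot(tree: TreeNode, name: str = "tree") -> str:
    """Graphviz DOT rendering of a tree (internal nodes show f_i <= thr)."""
    lines = [f"digraph {name} {{", "  node [shape=box];"]
    counter = [0]

    def walk(node: TreeNode) -> int:
        idx = counter[0]
        counter[0] += 1
        if node.is_leaf:
            lines.append(f'  n{idx} [label="C{node.label}\\n'
                         f'n={node.n_samples}", shape=ellipse];')
        else:
            lines.append(f'  n{idx} [label="f{node.point.feature_index} '
                         f'<= {node.point.threshold:.4g}"];')
            li = walk(node.left)
            ri = walk(node.right)
            lines.append(f'  n{idx} -> n{li} [label="yes"];')
            lines.append(f'  n{idx} -> n{ri} [label="no"];')
        return idx

    walk(tree)
    lines.append("}")
    return "\n".join(lines)
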