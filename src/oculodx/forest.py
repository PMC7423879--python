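"""Segmentation-point random forest with bootstrap and out-of-bag testing.

Each of the n_trees trees is grown on a bootstrap resample (N draws with
replacement) of the training set.  At every branch node,
floor(log2(M * (N-1))) segmentation points are drawn uniformly without
replacement from the tree's pool of not-yet-used ("unmarked") points; the
draw's best gain-rate point branches the node and is marked for the rest
of that tree.  Trees grow unpruned to purity.  Prediction is a majority
vote over trees (ties to the lowest class index); samples left out of a
tree's bootstrap form its out-of-bag (OOB) test set.

Per-tree random streams are spawned from the master seed with
``numpy.random.SeedSequence``, so the forest is reproducible regardless of
construction order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import c45
from .c45 import SegmentationPoint, TreeNode


@dataclass
class TreeRecord:
    tree: TreeNode
    in_bag: np.ndarray   # N bootstrap indices, with multiplicity
    oob: np.ndarray      # indices never drawn
    marked: list[SegmentationPoint]


@dataclass
class Forest:
    trees: list[TreeRecord]
    n_classes: int
    n_features: int
    n_candidates: int
    seed_entropy: str = ""

    @property
    def n_trees(self) -> int:
        return len(self.trees)


def bootstrap_sample(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """N uniform draws with replacement; OOB = indices never drawn."""
    if n < 1:
        raise ValueError("need at least one sample")
    in_bag = rng.integers(0, n, size=n)
    oob = np.setdiff1d(np.arange(n), in_bag)
    return in_bag, oob


def candidate_count(m_feat: int, n: int) -> int:
    """Per-node random draw size: floor(log2(M * (N-1)))."""
    if n < 2:
        raise ValueError("need N >= 2 samples")
    pool = m_feat * (n - 1)
    if pool < 2:
        raise ValueError("segmentation-point pool too small")
    return int(np.floor(np.log2(pool)))


def build_random_tree(
    X: np.ndarray,
    y: np.ndarray,
    seed: int | np.random.SeedSequence,
    n_candidates: int | None = None,
    n_classes: int | None = None,
) -> TreeRecord:
    """Bootstrap + randomized candidate draws -> one unpruned tree.

    At each node ``n_candidates`` points are drawn without replacement from
    the unmarked pool (fewer if the pool is smaller); points that are
    degenerate on the node's samples are discarded without redraw, so a
    node may effectively see fewer valid candidates.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n, m = X.shape
    if n_candidates is None:
        n_candidates = candidate_count(m, n)
    n_classes = n_classes or int(y.max())
    rng = np.random.default_rng(seed)

    in_bag, oob = bootstrap_sample(n, rng)
    Xb, yb = X[in_bag], y[in_bag]
    candidates = c45.enumerate_segmentation_points(Xb)

    def policy(pool: list[SegmentationPoint]) -> list[SegmentationPoint]:
        if len(pool) <= n_candidates:
            return list(pool)
        idx = rng.choice(len(pool), size=n_candidates, replace=False)
        return [pool[i] for i in sorted(idx)]

    marked: set[SegmentationPoint] = set()
    tree = c45.build_tree(Xb, yb, candidates=candidates,
                          candidate_policy=policy, marked=marked,
                          n_classes=n_classes)
    return TreeRecord(tree=tree, in_bag=in_bag, oob=oob,
                      marked=sorted(marked))


def build_forest(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 20,
    seed: int | np.random.SeedSequence = 0,
    n_candidates: int | None = None,
) -> Forest:
    """Grow ``n_trees`` independent randomized trees from a master seed."""
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n, m = X.shape
    if n_candidates is None:
        n_candidates = candidate_count(m, n)
    n_classes = int(y.max())
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    records = [build_random_tree(X, y, child, n_candidates, n_classes)
               for child in ss.spawn(n_trees)]
    return Forest(trees=records, n_classes=n_classes, n_features=m,
                  n_candidates=n_candidates, seed_entropy=str(ss.entropy))


def forest_votes(forest: Forest, features: np.ndarray) -> np.ndarray:
    """Per-class vote counts (index l-1 holds votes for class l)."""
    x = np.asarray(features, dtype=float)
    if x.shape[-1] != forest.n_features:
        raise ValueError(f"expected {forest.n_features} features, "
                         f"got {x.shape[-1]}")
    votes = np.zeros(forest.n_classes, dtype=int)
    for rec in forest.trees:
        votes[c45.classify(rec.tree, x) - 1] += 1
    return votes


def forest_predict(forest: Forest,
                   features: np.ndarray) -> tuple[int, np.ndarray]:
    """Majority-vote label (ties -> lowest class index) and vote counts."""
    votes = forest_votes(forest, features)
    return int(np.argmax(votes) + 1), votes


def predict_many(forest: Forest, X: np.ndarray) -> np.ndarray:
    return np.array([forest_predict(forest, x)[0] for x in np.asarray(X, float)])


def vote_fractions(forest: Forest, X: np.ndarray) -> np.ndarray:
    """(n, W) matrix of per-class vote fractions — the forest's soft scores."""
    return np.stack([forest_votes(forest, x) / forest.n_trees
                     for x in np.asarray(X, float)])


@dataclass
class OOBResult:
    accuracy: float
    predictions: dict[int, int]   # sample index -> OOB-voted label
    never_oob: list[int]          # samples in every bootstrap, not evaluable


def oob_evaluate(forest: Forest, X: np.ndarray, y: np.ndarray) -> OOBResult:
    """Out-of-bag accuracy: each sample judged only by trees that never saw it."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(X)
    votes = np.zeros((n, forest.n_classes), dtype=int)
    seen = np.zeros(n, dtype=bool)
    for rec in forest.trees:
        for i in rec.oob:
            votes[i, c45.classify(rec.tree, X[i]) - 1] += 1
            seen[i] = True
    if not seen.any():
        raise ValueError("no sample is out-of-bag for any tree")
    preds = {int(i): int(np.argmax(votes[i]) + 1)
             for i in range(n) if seen[i]}
    correct = sum(preds[i] == y[i] for i in preds)
    return OOBResult(accuracy=correct / len(preds), predictions=preds,
                     never_oob=[int(i) for i in range(n) if not seen[i]])


# ---- serialization -------------------------------------------------------

def save_forest(forest: Forest, path: str | Path) -> None:
    bundle = {
        "n_classes": forest.n_classes,
        "n_features": forest.n_features,
        "n_candidates": forest.n_candidates,
        "seed_entropy": forest.seed_entropy,
        "trees": [{
            "tree": c45.tree_to_dict(rec.tree),
            "in_bag": rec.in_bag.tolist(),
            "oob": rec.oob.tolist(),
            "marked": [[p.feature_index, p.threshold] for p in rec.marked],
        } for rec in forest.trees],
    }
    Path(path).write_text(json.dumps(bundle))


def load_forest(path: str | Path) -> Forest:
    bundle = json.loads(Path(path).read_text())
    trees = [TreeRecord(
        tree=c45.tree_from_dict(t["tree"]),
        in_bag=np.array(t["in_bag"], dtype=int),
        oob=np.array(t["oob"], dtype=int),
        marked=[SegmentationPoint(f, thr) for f, thr in t["marked"]],
    ) for t in bundle["trees"]]
    return Forest(trees=trees, n_classes=bundle["n_classes"],
                  n_features=bundle["n_features"],
                  n_candidates=bundle["n_candidates"],
                  seed_entropy=bundle.get("seed_entropy", ""))
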