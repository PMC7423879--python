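"""Evaluation: accuracy, one-vs-rest precision/recall/F-score, ROC/AUC.

The W-class problem is reported as W one-vs-rest binary problems.  ROC
curves come from a threshold sweep over the distinct positive-class
scores; hard 0/1 scores (a single decision tree's label indicator) yield
exactly three curve points — two line segments — while forest vote
fractions yield a finer curve.  AUC is the trapezoid-rule area.  Macro
averaging interpolates the per-class curves on the union grid of their
FPR breakpoints; micro averaging pools every (score, indicator) pair into
one curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np


def confusion_matrix(truth, predicted, n_classes: int | None = None) -> np.ndarray:
    """W x W counts; entry (i, j) = truth class i+1 predicted as j+1."""
    t = np.asarray(truth, dtype=int)
    p = np.asarray(predicted, dtype=int)
    if t.shape != p.shape:
        raise ValueError("truth and prediction lengths differ")
    w = n_classes or int(max(t.max(), p.max()))
    if t.min() < 1 or p.min() < 1 or t.max() > w or p.max() > w:
        raise ValueError(f"labels must lie in 1..{w}")
    cm = np.zeros((w, w), dtype=int)
    np.add.at(cm, (t - 1, p - 1), 1)
    return cm


def one_vs_rest_metrics(confusion: np.ndarray,
                        positive_class: int) -> tuple[float, float, float]:
    """(precision, recall, F-score) for one class vs the rest; 0/0 -> 0."""
    cm = np.asarray(confusion)
    i = positive_class - 1
    if not (0 <= i < cm.shape[0]):
        raise ValueError("positive_class out of range")
    tp = cm[i, i]
    fp = cm[:, i].sum() - tp
    fn = cm[i, :].sum() - tp
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f = (2 * precision * recall / (precision + recall)
         if precision + recall > 0 else 0.0)
    return float(precision), float(recall), float(f)


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    @property
    def n_segments(self) -> int:
        return len(self.fpr) - 1


def roc_curve(scores, truth, positive_class: int = 1) -> RocCurve:
    """Threshold sweep over distinct scores; AUC by the trapezoid rule.

    The curve runs from (0, 0) (threshold above every score) to (1, 1);
    collinear interior points on the same sweep step are kept only at the
    distinct-score breakpoints, so binary 0/1 scores give exactly three
    points.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth)
    pos = (t == positive_class)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative sample")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    pos_sorted = pos[order]
    tps = np.cumsum(pos_sorted)
    fps = np.cumsum(~pos_sorted)
    # keep the last index of each distinct-score run
    distinct = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, auc=auc)


def average_roc(per_class_scores: list[np.ndarray], truth,
                mode: str = "macro", n_classes: int | None = None) -> RocCurve:
    """Macro or micro average of the W one-vs-rest ROC curves.

    ``per_class_scores[l]`` holds every sample's score for class l+1.
    Macro: mean per-class TPR on the union grid of FPR breakpoints.
    Micro: one ROC over the pooled (score, is-this-class) pairs.
    """
    t = np.asarray(truth)
    w = n_classes or len(per_class_scores)
    if mode == "micro":
        pooled_scores = np.concatenate(
            [np.asarray(per_class_scores[l]) for l in range(w)])
        pooled_truth = np.concatenate(
            [(t == l + 1).astype(int) for l in range(w)])
        return roc_curve(pooled_scores, pooled_truth, positive_class=1)
    if mode != "macro":
        raise ValueError("mode must be 'macro' or 'micro'")
    curves = [roc_curve(per_class_scores[l], t, positive_class=l + 1)
              for l in range(w)]
    grid = np.unique(np.concatenate([c.fpr for c in curves]))
    mean_tpr = np.mean([np.interp(grid, c.fpr, c.tpr) for c in curves], axis=0)
    if mean_tpr[0] > 0.0:
        # interpolation at a shared vertical segment loses the (0, 0)
        # anchor; restore it so every curve starts at the origin
        grid = np.r_[0.0, grid]
        mean_tpr = np.r_[0.0, mean_tpr]
    return RocCurve(fpr=grid, tpr=mean_tpr,
                    auc=float(np.trapezoid(mean_tpr, grid)))


@dataclass
class EvalReport:
    """Consolidated report for one classifier on one test set."""

    accuracy: float
    confusion: np.ndarray
    per_class: dict[int, dict[str, float]]
    roc: dict[str, RocCurve] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "confusion": self.confusion.tolist(),
            "per_class": {str(k): v for k, v in self.per_class.items()},
            "roc": {k: {"fpr": c.fpr.tolist(), "tpr": c.tpr.tolist(),
                        "auc": c.auc} for k, c in self.roc.items()},
        }


def evaluate(truth, predicted, scores: np.ndarray | None = None,
             n_classes: int | None = None) -> EvalReport:
    """Full report: accuracy, per-class PRF, and (if scores given) ROC/AUC.

    ``scores`` is an (n, W) matrix of per-class scores (vote fractions or
    probabilities); when omitted, ROC curves are built from the hard label
    indicators.
    """
    t = np.asarray(truth, dtype=int)
    p = np.asarray(predicted, dtype=int)
    cm = confusion_matrix(t, p, n_classes)
    w = cm.shape[0]
    acc = float(np.trace(cm) / cm.sum())
    per_class = {}
    for l in range(1, w + 1):
        pr, rc, f = one_vs_rest_metrics(cm, l)
        per_class[l] = {"precision": pr, "recall": rc, "fscore": f}
    if scores is None:
        scores = np.stack([(p == l).astype(float)
                           for l in range(1, w + 1)], axis=1)
    roc = {}
    col = [np.asarray(scores)[:, l] for l in range(w)]
    for l in range(w):
        roc[f"C{l + 1}"] = roc_curve(col[l], t, positive_class=l + 1)
    roc["macro"] = average_roc(col, t, "macro", w)
    roc["micro"] = average_roc(col, t, "micro", w)
    return EvalReport(accuracy=acc, confusion=cm, per_class=per_class, roc=roc)


def plot_report(report: EvalReport, path=None, title: str = ""):
    """Optional ROC figure (per-class + macro/micro), saved if path given."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, curve in report.roc.items():
        ax.plot(curve.fpr, curve.tpr, label=f"{name} (AUC={curve.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title(title or f"ROC (accuracy {report.accuracy:.3f})")
    ax.legend(fontsize=8)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
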