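"""Confusion-matrix statistics for binary segmentation masks.

Every score here is derived from the four pixel counts (TP, TN, FP, FN) of a
ground-truth/prediction pair, computed in exact integer arithmetic and only
then converted to a real-valued score — there is no intermediate rounding,
so the scores agree exactly with a brute-force per-pixel recount.

Degenerate inputs are governed by an explicit :class:`EdgePolicy` rather
than silent conventions, because mapping an undefined ratio to 1.0 inflates
aggregate scores on heavily imbalanced datasets (an all-background image
makes sensitivity 0/0; calling that 1.0 rewards the model for nothing). The
default policy records such scores as undefined and excludes them from
aggregation; the one exception is overlap between two empty masks, which is
genuine perfect agreement and defaults to 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

__all__ = [
    "ConfusionCounts",
    "EdgePolicy",
    "DEFAULT_POLICY",
    "confusion_counts",
    "dsc",
    "iou",
    "sensitivity",
    "specificity",
    "accuracy",
    "kappa",
    "auc_binary",
    "roc_curve",
    "CONFUSION_METRICS",
    "METRIC_NAMES",
    "METRIC_RANGES",
    "edge_note",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel-level TP/TN/FP/FN totals for one binary (sample, class) pair."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    @property
    def n(self) -> int:
        """Total pixel count; always tp + tn + fp + fn."""
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


@dataclass(frozen=True)
class EdgePolicy:
    """What to return when a metric's formula degenerates.

    ``zero_denominator`` applies when a rate's denominator is zero (e.g.
    sensitivity on an empty ground truth): ``None`` records the score as
    undefined, or a fixed 0.0 / 1.0 can be substituted. ``both_empty_overlap``
    applies to overlap scores (DSC, IoU) when both masks are empty.
    """

    zero_denominator: Optional[float] = None
    both_empty_overlap: Optional[float] = 1.0


DEFAULT_POLICY = EdgePolicy()


def confusion_counts(truth: np.ndarray, pred: np.ndarray) -> ConfusionCounts:
    """Count TP/TN/FP/FN between two boolean masks of identical shape."""
    truth = np.asarray(truth, dtype=bool)
    pred = np.asarray(pred, dtype=bool)
    if truth.shape != pred.shape:
        raise ValueError(
            f"shape mismatch: truth {truth.shape} vs prediction {pred.shape}"
        )
    tp = int(np.count_nonzero(truth & pred))
    fp = int(np.count_nonzero(~truth & pred))
    fn = int(np.count_nonzero(truth & ~pred))
    tn = truth.size - tp - fp - fn
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def dsc(c: ConfusionCounts, policy: EdgePolicy = DEFAULT_POLICY) -> Optional[float]:
    """Dice similarity coefficient 2·TP / (2·TP + FP + FN).

    The F1 score of the pixel classification; ignores true negatives, which
    makes it robust to the extreme background prevalence of medical images.
    Both masks empty -> ``policy.both_empty_overlap``.
    """
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return policy.both_empty_overlap
    return 2 * c.tp / denom


def iou(c: ConfusionCounts, policy: EdgePolicy = DEFAULT_POLICY) -> Optional[float]:
    """Intersection-over-Union (Jaccard) TP / (TP + FP + FN)."""
    denom = c.tp + c.fp + c.fn
    if denom == 0:
        return policy.both_empty_overlap
    return c.tp / denom


def sensitivity(
    c: ConfusionCounts, policy: EdgePolicy = DEFAULT_POLICY
) -> Optional[float]:
    """True-positive rate TP / (TP + FN); undefined on an empty ground truth."""
    denom = c.tp + c.fn
    if denom == 0:
        return policy.zero_denominator
    return c.tp / denom


def specificity(
    c: ConfusionCounts, policy: EdgePolicy = DEFAULT_POLICY
) -> Optional[float]:
    """True-negative rate TN / (TN + FP); undefined on an all-foreground truth."""
    denom = c.tn + c.fp
    if denom == 0:
        return policy.zero_denominator
    return c.tn / denom


def accuracy(
    c: ConfusionCounts, policy: EdgePolicy = DEFAULT_POLICY
) -> float:
    """Rand index (TP + TN) / n.

    Always defined, but inflated by the dominant background class: an
    all-background prediction on an image with ROI fraction r scores 1 - r.
    """
    return (c.tp + c.tn) / c.n


def kappa(c: ConfusionCounts, policy: EdgePolicy = DEFAULT_POLICY) -> Optional[float]:
    """Cohen's kappa: chance-corrected agreement (p_o - p_e) / (1 - p_e).

    p_o = (TP + TN)/n and p_e = [(TP+FN)(TP+FP) + (FP+TN)(FN+TN)] / n^2,
    the standard marginal-product expected agreement with no bias or
    prevalence correction. When both raters are constant and identical
    (p_e = 1 with perfect agreement) the score is 1.0; constant-but-disagreeing
    marginals cannot make p_e = 1, so the remaining p_e = 1 case falls to the
    zero-denominator policy.
    """
    n = c.n
    # exact integer arithmetic; n^2 stays below 2^53 for any raster that fits memory
    num_o = c.tp + c.tn
    num_e = (c.tp + c.fn) * (c.tp + c.fp) + (c.fp + c.tn) * (c.fn + c.tn)
    p_o = num_o / n
    p_e = num_e / (n * n)
    if num_e == n * n:  # p_e == 1 exactly
        if num_o == n:
            return 1.0
        return policy.zero_denominator
    return (p_o - p_e) / (1.0 - p_e)


def auc_binary(
    c: ConfusionCounts, policy: EdgePolicy = DEFAULT_POLICY
) -> Optional[float]:
    """AUC of the two-point ROC through a hard binary prediction.

    The trapezoid through (0,0), (FPR, TPR), (1,1) has area
    (sensitivity + specificity) / 2. If either rate is undefined under the
    policy the result is undefined too.
    """
    sens = sensitivity(c, policy)
    spec = specificity(c, policy)
    if sens is None or spec is None:
        return None
    return (sens + spec) / 2.0


def roc_curve(
    truth: np.ndarray,
    prob: np.ndarray,
    thresholds: Sequence[float],
) -> Tuple[List[Tuple[float, float]], float]:
    """ROC points and trapezoidal AUC from a per-pixel probability map.

    For each threshold t the prediction is ``prob >= t``; the resulting
    (FPR, TPR) points, with (0,0) and (1,1) appended, are sorted by FPR
    (ties by TPR) and integrated by the trapezoid rule.

    Requires at least one positive and one negative pixel in the truth.
    """
    truth = np.asarray(truth, dtype=bool)
    prob = np.asarray(prob, dtype=float)
    if prob.shape != truth.shape:
        raise ValueError(
            f"shape mismatch: probability map {prob.shape} vs truth {truth.shape}"
        )
    if len(thresholds) == 0:
        raise ValueError("threshold list must be non-empty")
    if prob.size and (prob.min() < 0.0 or prob.max() > 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    pos = int(np.count_nonzero(truth))
    neg = truth.size - pos
    if pos == 0 or neg == 0:
        raise ValueError(
            "ROC requires both positive and negative pixels in the ground truth"
        )
    points = {(0.0, 0.0), (1.0, 1.0)}
    for t in thresholds:
        pred = prob >= t
        tp = int(np.count_nonzero(truth & pred))
        fp = int(np.count_nonzero(~truth & pred))
        points.add((fp / neg, tp / pos))
    ordered = sorted(points)
    auc = 0.0
    for (x0, y0), (x1, y1) in zip(ordered, ordered[1:]):
        auc += (x1 - x0) * (y0 + y1) / 2.0
    return ordered, auc


#: Confusion-matrix-based metrics addressable by registry name.
CONFUSION_METRICS: Dict[
    str, Callable[[ConfusionCounts, EdgePolicy], Optional[float]]
] = {
    "dsc": dsc,
    "iou": iou,
    "sens": sensitivity,
    "spec": specificity,
    "acc": accuracy,
    "kappa": kappa,
    "auc": auc_binary,
}

#: All registered metric names, including the distance-based AHD.
METRIC_NAMES: Tuple[str, ...] = tuple(CONFUSION_METRICS) + ("ahd",)

#: Natural value range per metric (AHD is unbounded above; None marks that).
METRIC_RANGES: Dict[str, Tuple[float, Optional[float]]] = {
    "dsc": (0.0, 1.0),
    "iou": (0.0, 1.0),
    "sens": (0.0, 1.0),
    "spec": (0.0, 1.0),
    "acc": (0.0, 1.0),
    "auc": (0.0, 1.0),
    "kappa": (-1.0, 1.0),
    "ahd": (0.0, None),
}


def edge_note(metric: str, c: ConfusionCounts, policy: EdgePolicy) -> str:
    """Human-readable provenance for a score produced by an edge policy."""
    if metric in ("dsc", "iou") and c.tp + c.fp + c.fn == 0:
        return f"both-empty overlap -> policy value {policy.both_empty_overlap}"
    if metric in ("sens", "auc") and c.tp + c.fn == 0:
        return "empty ground truth: zero-denominator policy"
    if metric in ("spec", "auc") and c.tn + c.fp == 0:
        return "all-foreground ground truth: zero-denominator policy"
    if metric == "kappa":
        n = c.n
        if (c.tp + c.fn) * (c.tp + c.fp) + (c.fp + c.tn) * (c.fn + c.tn) == n * n:
            if c.tp + c.tn == n:
                return "constant identical raters: kappa fixed at 1.0"
            return "chance agreement 1: zero-denominator policy"
    return ""
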