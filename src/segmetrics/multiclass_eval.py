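"""Multi-class segmentation scoring via one-vs-rest reduction.

Binary metrics applied blindly to multi-class label maps are biased, most of
all under class imbalance: including a near-perfectly-predicted background
class in a macro average pushes the mean upwards and makes weak ROI
segmentation look strong (confirmation bias). This module therefore scores
each class individually — one-vs-rest against the rest of the label map —
and offers two aggregation routes:

* macro averaging: per-class scores, unweighted mean, with an explicit
  switch to drop the background class (a guideline warning fires whenever
  background is included);
* micro averaging: one-vs-rest confusion counts pooled across classes, the
  metric formula applied once to the pooled counts. The distance-based AHD
  has no confusion counts and hence no micro form.

Undefined per-class values (edge-policy cases) are excluded from macro means
and their count reported, never imputed — imputing in either direction is
exactly the score inflation the one-vs-rest machinery is meant to expose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .confusion_metrics import (
    CONFUSION_METRICS,
    DEFAULT_POLICY,
    ConfusionCounts,
    EdgePolicy,
    confusion_counts,
    edge_note,
)
from .distance_metrics import average_hausdorff
from .masks_io import LabelMask, ScoreRecord, binarize, validate_pair

__all__ = [
    "ClassConfig",
    "MacroResult",
    "GuidelineWarning",
    "per_class_scores",
    "macro_average",
    "micro_average",
]


class GuidelineWarning(UserWarning):
    """A configuration conflicts with recommended evaluation practice."""


@dataclass(frozen=True)
class ClassConfig:
    """The label set under evaluation and how background is aggregated."""

    labels: Tuple[int, ...] = (0, 1)
    background_label: int = 0
    include_background_in_macro: bool = True

    def __post_init__(self) -> None:
        labels = tuple(int(l) for l in self.labels)
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate class labels in {labels}")
        if self.background_label not in labels:
            raise ValueError(
                f"background label {self.background_label} not in label set {labels}"
            )
        object.__setattr__(self, "labels", labels)

    def macro_labels(self) -> Tuple[int, ...]:
        if self.include_background_in_macro:
            return self.labels
        return tuple(l for l in self.labels if l != self.background_label)


@dataclass(frozen=True)
class MacroResult:
    """A macro average plus how many undefined class scores were excluded."""

    value: Optional[float]
    n_excluded: int


def _score_one_class(
    truth: LabelMask,
    pred: LabelMask,
    label: int,
    metric: str,
    policy: EdgePolicy,
    spacing: Optional[Sequence[float]],
    ahd_mode: str,
) -> Tuple[Optional[float], str]:
    t_bin = binarize(truth, label)
    p_bin = binarize(pred, label)
    if metric == "ahd":
        value = average_hausdorff(t_bin, p_bin, spacing=spacing, mode=ahd_mode)
        note = "" if value is not None else "one empty point set: AHD undefined"
        if value == 0.0 and not t_bin.any():
            note = "both point sets empty: AHD 0"
        return value, note
    counts = confusion_counts(t_bin, p_bin)
    value = CONFUSION_METRICS[metric](counts, policy)
    return value, edge_note(metric, counts, policy)


def per_class_scores(
    truth: LabelMask,
    pred: LabelMask,
    metrics: Sequence[str],
    cfg: ClassConfig,
    sample_id: str = "",
    policy: EdgePolicy = DEFAULT_POLICY,
    spacing: Optional[Sequence[float]] = None,
    ahd_mode: str = "all-foreground",
) -> List[ScoreRecord]:
    """Score every configured class one-vs-rest for every requested metric.

    Returns exactly ``len(cfg.labels) * len(metrics)`` records, in label-major
    order. AHD is computed only when explicitly requested.
    """
    validate_pair(truth, pred, labels=cfg.labels)
    unknown = [m for m in metrics if m not in CONFUSION_METRICS and m != "ahd"]
    if unknown:
        raise ValueError(
            f"unknown metric name(s) {unknown}; registered: "
            f"{sorted(CONFUSION_METRICS) + ['ahd']}"
        )
    records: List[ScoreRecord] = []
    for label in cfg.labels:
        for metric in metrics:
            value, note = _score_one_class(
                truth, pred, label, metric, policy, spacing, ahd_mode
            )
            records.append(
                ScoreRecord(
                    sample_id=sample_id,
                    class_label=label,
                    metric=metric,
                    value=value,
                    policy_note=note,
                )
            )
    return records


def macro_average(records: Sequence[ScoreRecord], cfg: ClassConfig) -> MacroResult:
    """Unweighted mean of per-class scores for one metric.

    Background is dropped when ``cfg.include_background_in_macro`` is false;
    including it fires a :class:`GuidelineWarning` because a well-predicted
    dominant background inflates the mean. Undefined scores are excluded and
    counted; if every score is excluded the macro average itself is undefined.
    """
    if not records:
        raise ValueError("macro average requires at least one record")
    metrics = {r.metric for r in records}
    if len(metrics) > 1:
        raise ValueError(f"records mix metrics {sorted(metrics)}")
    if cfg.include_background_in_macro:
        warnings.warn(
            "macro average includes the background class; a well-predicted "
            "dominant background inflates the mean (confirmation bias) — "
            "consider include_background_in_macro=False",
            GuidelineWarning,
            stacklevel=2,
        )
    included = set(cfg.macro_labels())
    values = [
        r.value
        for r in records
        if r.class_label in included
    ]
    defined = [v for v in values if v is not None]
    n_excluded = len(values) - len(defined)
    if not defined:
        return MacroResult(value=None, n_excluded=n_excluded)
    return MacroResult(value=float(np.mean(defined)), n_excluded=n_excluded)


def micro_average(
    truth: LabelMask,
    pred: LabelMask,
    metric: str,
    cfg: ClassConfig,
    policy: EdgePolicy = DEFAULT_POLICY,
    include_background: bool = True,
) -> Optional[float]:
    """Pool one-vs-rest confusion counts across classes, then apply the metric.

    Counts (TP/FP/FN/TN) are summed over the included classes' one-vs-rest
    matrices and the metric formula is applied once to the pooled counts.
    Only confusion-matrix metrics have a micro form; requesting ``ahd``
    raises.
    """
    if metric == "ahd":
        raise ValueError("AHD is distance-based and has no micro-averaged form")
    if metric not in CONFUSION_METRICS:
        raise ValueError(f"unknown metric name {metric!r}")
    validate_pair(truth, pred, labels=cfg.labels)
    labels = (
        cfg.labels
        if include_background
        else tuple(l for l in cfg.labels if l != cfg.background_label)
    )
    if not labels:
        raise ValueError("no classes left to pool after background exclusion")
    pooled = ConfusionCounts(0, 0, 0, 0)
    for label in labels:
        pooled = pooled + confusion_counts(binarize(truth, label), binarize(pred, label))
    return CONFUSION_METRICS[metric](pooled, policy)
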