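"""Guideline-compliant batch evaluation: scoring, summaries, visualization.

One call — :func:`run_evaluation` — scores every ground-truth/prediction
pair in two directories, writes a per-sample per-class score table, macro
and micro aggregates, a distribution summary per metric (quantiles plus
histogram — the data behind a histogram, box or violin plot), overlay
rasters for a seeded *uniform* random sample of pairs (never score-ranked,
so high scorers cannot be cherry-picked), and a manifest that makes the run
byte-for-byte reproducible.

Reporting conventions:

* DSC is the headline metric and is listed first; the default metric set is
  ``dsc, iou, sens, spec``. Accuracy is computed only on request and is
  flagged with a class-imbalance caveat, since a dominant background makes
  it high in any segmentation context.
* AHD values above the clip ceiling (default 250 pixels) are clipped in
  summaries only, with the affected fraction reported; the raw CSV always
  keeps unclipped values.
* Quantiles use linear interpolation between order statistics; histogram
  bins are equal-width over the metric's natural range with the final bin
  right-closed. Undefined scores never enter quantiles, means or
  histograms; they are counted separately.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import imageio.v3 as iio
import numpy as np

from . import __version__
from .confusion_metrics import DEFAULT_POLICY, METRIC_RANGES, EdgePolicy
from .masks_io import (
    LabelMask,
    ScoreRecord,
    binarize,
    read_mask,
    validate_pair,
    write_scores,
)
from .multiclass_eval import ClassConfig, macro_average, micro_average, per_class_scores

__all__ = [
    "DistributionSummary",
    "RunConfig",
    "DEFAULT_METRICS",
    "clip_metric",
    "summarize_distribution",
    "select_visual_samples",
    "render_overlay",
    "run_evaluation",
]

DEFAULT_METRICS: Tuple[str, ...] = ("dsc", "iou", "sens", "spec")

#: TP / FP / FN tint colors (RGB) and opacity for color overlays.
OVERLAY_PALETTE: Dict[str, Tuple[int, int, int]] = {
    "tp": (0, 200, 0),
    "fp": (220, 0, 0),
    "fn": (0, 80, 255),
}
OVERLAY_OPACITY = 0.5


@dataclass(frozen=True)
class DistributionSummary:
    """Quantiles and histogram of one metric across a dataset."""

    metric: str
    class_label: Union[int, str]
    count: int
    n_undefined: int
    min: float
    q1: float
    median: float
    q3: float
    max: float
    mean: float
    bin_width: float
    histogram: Tuple[Tuple[float, int], ...]  # (bin left edge, count)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["histogram"] = [[edge, cnt] for edge, cnt in self.histogram]
        return d


@dataclass
class RunConfig:
    """Configuration of one batch evaluation run."""

    truth_dir: Union[str, Path]
    pred_dir: Union[str, Path]
    output_dir: Union[str, Path]
    metrics: Tuple[str, ...] = DEFAULT_METRICS
    labels: ClassConfig = field(default_factory=ClassConfig)
    policy: EdgePolicy = DEFAULT_POLICY
    spacing: Optional[Tuple[float, ...]] = None
    ahd_mode: str = "all-foreground"
    ahd_clip: Optional[float] = 250.0
    macro: bool = True
    micro: bool = False
    n_visual_samples: int = 3
    histogram_bins: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.metrics:
            raise ValueError("metric list must be non-empty")
        self.metrics = tuple(self.metrics)
        if self.ahd_clip is not None and self.ahd_clip <= 0:
            raise ValueError("AHD clip ceiling must be positive")


def clip_metric(
    records: Sequence[ScoreRecord], metric: str, ceiling: float
) -> Tuple[List[ScoreRecord], float]:
    """Clip one metric's values at a ceiling, reporting the affected fraction.

    Values above the ceiling are replaced by it; the affected fraction is
    (#replaced) / (#defined records of that metric). Used at reporting time
    so a handful of runaway distance values cannot dominate a distribution
    plot; raw records elsewhere stay unclipped.
    """
    if ceiling <= 0:
        raise ValueError("clip ceiling must be positive")
    out: List[ScoreRecord] = []
    n_defined = 0
    n_clipped = 0
    for r in records:
        if r.metric == metric and r.value is not None:
            n_defined += 1
            if r.value > ceiling:
                n_clipped += 1
                r = dataclasses.replace(
                    r,
                    value=float(ceiling),
                    policy_note=(r.policy_note + "; " if r.policy_note else "")
                    + f"clipped to {ceiling:g}",
                )
        out.append(r)
    fraction = n_clipped / n_defined if n_defined else 0.0
    return out, fraction


def summarize_distribution(
    records: Sequence[ScoreRecord],
    bins: int = 20,
    value_range: Optional[Tuple[float, float]] = None,
) -> DistributionSummary:
    """Summarize one (metric, class) group of records.

    Quantiles use linear interpolation; the histogram has ``bins`` equal
    bins over ``value_range`` (default: the metric's natural range, e.g.
    [0, 1] for overlap scores, [-1, 1] for kappa) with the final bin
    right-closed. Requires at least one defined value.
    """
    if not records:
        raise ValueError("cannot summarize an empty record list")
    metrics = {r.metric for r in records}
    classes = {r.class_label for r in records}
    if len(metrics) > 1 or len(classes) > 1:
        raise ValueError(
            f"records must share one (metric, class); got {sorted(metrics)} "
            f"x {sorted(map(str, classes))}"
        )
    metric = next(iter(metrics))
    values = np.array([r.value for r in records if r.value is not None], dtype=float)
    n_undefined = len(records) - values.size
    if values.size == 0:
        raise ValueError(f"all {metric} records are undefined; nothing to summarize")
    if value_range is None:
        lo, hi = METRIC_RANGES.get(metric, (None, None))
        if lo is None or hi is None:
            lo = 0.0 if metric == "ahd" else float(values.min())
            hi = float(values.max())
            if hi <= lo:
                hi = lo + 1.0
        value_range = (float(lo), float(hi))
    lo, hi = value_range
    # edges via the convex combination (lo*(b-i)+hi*i)/b so that values lying
    # exactly on a decimal edge land in the upper (left-closed) bin
    edges = np.array([(lo * (bins - i) + hi * i) / bins for i in range(bins + 1)])
    counts, edges = np.histogram(values, bins=edges)
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75], method="linear")
    return DistributionSummary(
        metric=metric,
        class_label=next(iter(classes)),
        count=int(values.size),
        n_undefined=int(n_undefined),
        min=float(values.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        max=float(values.max()),
        mean=float(values.mean()),
        bin_width=float(edges[1] - edges[0]),
        histogram=tuple((float(e), int(c)) for e, c in zip(edges[:-1], counts)),
    )


def select_visual_samples(
    sample_ids: Sequence[str], n: int, seed: int
) -> List[str]:
    """Seeded uniform draw of samples for visualization.

    The draw never sees scores, so it cannot cherry-pick high-scoring
    samples; with a fixed seed it is reproducible.
    """
    ids = list(sample_ids)
    n = min(n, len(ids))
    if n <= 0:
        return []
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(ids), size=n, replace=False)
    return [ids[i] for i in sorted(chosen)]


def _to_uint8_gray(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if np.issubdtype(image.dtype, np.floating):
        image = np.clip(image, 0.0, 1.0) * 255.0
    return image.astype(np.uint8)


def render_overlay(
    truth: np.ndarray,
    pred: np.ndarray,
    path: Union[str, Path],
    style: str = "binary-panels",
    image: Optional[np.ndarray] = None,
) -> Path:
    """Write a visual truth-vs-prediction comparison raster.

    ``binary-panels`` places black/white truth and prediction side by side
    (separated by a 2-pixel grey gutter). ``color-overlay`` tints the base
    grayscale image per pixel category — TP green, FP red, FN blue — at
    fixed opacity; it requires the base image.
    """
    truth = np.asarray(truth, dtype=bool)
    pred = np.asarray(pred, dtype=bool)
    if truth.shape != pred.shape:
        raise ValueError(
            f"shape mismatch: truth {truth.shape} vs prediction {pred.shape}"
        )
    if truth.ndim != 2:
        raise ValueError("overlay rendering is defined for 2D masks")
    path = Path(path)
    if style == "binary-panels":
        gutter = np.full((truth.shape[0], 2), 128, dtype=np.uint8)
        panel = np.concatenate(
            [truth.astype(np.uint8) * 255, gutter, pred.astype(np.uint8) * 255],
            axis=1,
        )
        iio.imwrite(path, panel)
    elif style == "color-overlay":
        if image is None:
            raise ValueError("color-overlay requires a base grayscale image")
        base = _to_uint8_gray(image)
        if base.shape != truth.shape:
            raise ValueError(
                f"base image shape {base.shape} does not match masks {truth.shape}"
            )
        rgb = np.stack([base] * 3, axis=-1).astype(float)
        categories = {
            "tp": truth & pred,
            "fp": ~truth & pred,
            "fn": truth & ~pred,
        }
        for name, mask in categories.items():
            color = np.asarray(OVERLAY_PALETTE[name], dtype=float)
            rgb[mask] = (1 - OVERLAY_OPACITY) * rgb[mask] + OVERLAY_OPACITY * color
        iio.imwrite(path, rgb.round().astype(np.uint8))
    else:
        raise ValueError(f"unknown overlay style {style!r}")
    return path


_MASK_SUFFIXES = (".png", ".tif", ".tiff")


def _list_masks(directory: Path) -> Dict[str, Path]:
    return {
        p.name: p
        for p in sorted(directory.iterdir())
        if p.suffix.lower() in _MASK_SUFFIXES
    }


def run_evaluation(cfg: RunConfig) -> List[ScoreRecord]:
    """Score every same-named truth/prediction mask pair and write reports.

    Outputs in ``cfg.output_dir``: ``scores.csv`` (raw, unclipped),
    ``summary.json`` (per-(metric, class) distribution summaries, AHD
    clipped at ``cfg.ahd_clip`` with the affected fraction reported),
    ``manifest.json`` (full config, seed, versions, palette), and
    ``overlays/*.png`` for the seeded visual sample. Returns the raw
    per-sample records including macro/micro aggregate rows.
    """
    truth_dir = Path(cfg.truth_dir)
    pred_dir = Path(cfg.pred_dir)
    out_dir = Path(cfg.output_dir)
    truth_files = _list_masks(truth_dir)
    pred_files = _list_masks(pred_dir)
    common = sorted(set(truth_files) & set(pred_files))
    if not common:
        raise ValueError(
            f"no matching mask filenames between {truth_dir} and {pred_dir}"
        )
    out_dir.mkdir(parents=True, exist_ok=True)

    records: List[ScoreRecord] = []
    pairs: Dict[str, Tuple[LabelMask, LabelMask]] = {}
    for name in common:
        try:
            truth = read_mask(truth_files[name])
            pred = read_mask(pred_files[name])
        except Exception as exc:
            raise ValueError(f"unreadable mask {name}: {exc}") from exc
        validate_pair(truth, pred, labels=cfg.labels.labels)
        pairs[name] = (truth, pred)
        sample_records = per_class_scores(
            truth,
            pred,
            metrics=cfg.metrics,
            cfg=cfg.labels,
            sample_id=name,
            policy=cfg.policy,
            spacing=cfg.spacing,
            ahd_mode=cfg.ahd_mode,
        )
        records.extend(sample_records)
        for metric in cfg.metrics:
            metric_records = [r for r in sample_records if r.metric == metric]
            if cfg.macro:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # background-inclusion choice is recorded per record
                    macro = macro_average(metric_records, cfg.labels)
                note = "macro average"
                if macro.n_excluded:
                    note += f" ({macro.n_excluded} undefined class score(s) excluded)"
                if not cfg.labels.include_background_in_macro:
                    note += ", background excluded"
                records.append(
                    ScoreRecord(name, "all", metric, macro.value, note)
                )
            if cfg.micro and metric != "ahd":
                micro = micro_average(
                    truth, pred, metric, cfg.labels, policy=cfg.policy
                )
                records.append(
                    ScoreRecord(name, "all", metric, micro, "micro average")
                )

    write_scores(records, out_dir / "scores.csv", format="csv")

    # summaries: per (metric, class) over per-class rows; AHD clipped first
    summary_records = list(records)
    clip_fraction: Optional[float] = None
    if cfg.ahd_clip is not None and "ahd" in cfg.metrics:
        summary_records, clip_fraction = clip_metric(
            summary_records, "ahd", cfg.ahd_clip
        )
    summaries: List[DistributionSummary] = []
    groups: Dict[Tuple[str, Union[int, str]], List[ScoreRecord]] = {}
    for r in summary_records:
        groups.setdefault((r.metric, r.class_label), []).append(r)
    for metric in cfg.metrics:
        for class_label in list(cfg.labels.labels) + (["all"] if cfg.macro else []):
            group = groups.get((metric, class_label))
            if not group or all(r.value is None for r in group):
                continue
            vrange = None
            if metric == "ahd":
                vrange = (0.0, float(cfg.ahd_clip)) if cfg.ahd_clip else None
            summaries.append(
                summarize_distribution(group, bins=cfg.histogram_bins, value_range=vrange)
            )
    summary_payload: dict = {
        "n_samples": len(common),
        "summaries": [s.to_dict() for s in summaries],
    }
    if clip_fraction is not None:
        summary_payload["ahd_clip"] = {
            "ceiling": cfg.ahd_clip,
            "affected_percent": round(100.0 * clip_fraction, 1),
        }
    if "acc" in cfg.metrics:
        summary_payload["caveats"] = [
            "accuracy rewards true negatives and is inflated by the dominant "
            "background class; do not interpret segmentation quality from it"
        ]
    (out_dir / "summary.json").write_text(
        json.dumps(summary_payload, indent=1) + "\n"
    )

    # anti-cherry-picking visualization: seeded uniform sample, never ranked
    overlay_dir = out_dir / "overlays"
    chosen = select_visual_samples(common, cfg.n_visual_samples, cfg.seed)
    if chosen:
        overlay_dir.mkdir(exist_ok=True)
    foreground_labels = [
        l for l in cfg.labels.labels if l != cfg.labels.background_label
    ]
    overlay_label = foreground_labels[0] if foreground_labels else cfg.labels.labels[0]
    for name in chosen:
        truth, pred = pairs[name]
        if truth.ndim != 2:
            continue  # overlays are defined for 2D rasters only
        render_overlay(
            binarize(truth, overlay_label),
            binarize(pred, overlay_label),
            overlay_dir / f"{Path(name).stem}_overlay.png",
            style="binary-panels",
        )

    manifest = {
        "segmetrics_version": __version__,
        "numpy_version": np.__version__,
        "seed": cfg.seed,
        "truth_dir": str(truth_dir),
        "pred_dir": str(pred_dir),
        "metrics": list(cfg.metrics),
        "labels": list(cfg.labels.labels),
        "background_label": cfg.labels.background_label,
        "include_background_in_macro": cfg.labels.include_background_in_macro,
        "policy": {
            "zero_denominator": cfg.policy.zero_denominator,
            "both_empty_overlap": cfg.policy.both_empty_overlap,
        },
        "spacing": list(cfg.spacing) if cfg.spacing else None,
        "ahd_mode": cfg.ahd_mode,
        "ahd_clip": cfg.ahd_clip,
        "macro": cfg.macro,
        "micro": cfg.micro,
        "histogram_bins": cfg.histogram_bins,
        "n_visual_samples": cfg.n_visual_samples,
        "visual_samples": chosen,
        "overlay_style": "binary-panels",
        "overlay_palette": OVERLAY_PALETTE,
        "overlay_opacity": OVERLAY_OPACITY,
        "n_samples": len(common),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return records
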