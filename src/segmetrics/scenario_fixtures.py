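"""Synthetic segmentation scenarios and the experiment dataset splitter.

This module is the package's complete offline data supply. It generates the
classic demonstration baselines against which metric behaviour is usually
illustrated —

* no segmentation: not a single pixel predicted as ROI,
* full segmentation: every pixel predicted as ROI,
* random segmentation: i.i.d. Bernoulli(p) prediction per pixel,
* perturbed: the ground truth translated and dilated/eroded, a stand-in for
  models at different stages of training (perturbation strength maps
  monotonically to DSC degradation) —

together with ground-truth masks of controlled geometry or controlled
background:ROI class ratio, covering the imbalance regimes typical of
medical imaging (from roughly 9:1 for a large ROI up to hundreds:1 for a
small lesion in a volumetric scan).

Every generator is driven by one scalar seed through ``numpy``'s default
PCG64 generator and never touches global RNG state, so outputs are
bit-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage

from .masks_io import LabelMask

__all__ = [
    "Rectangle",
    "Ellipse",
    "Perturbation",
    "ScenarioSpec",
    "SCENARIO_NAMES",
    "make_truth",
    "class_ratio",
    "predict_scenario",
    "split_dataset",
]

SCENARIO_NAMES = (
    "no-segmentation",
    "full-segmentation",
    "random-segmentation",
    "perturbed",
)


@dataclass(frozen=True)
class Rectangle:
    """Axis-aligned box ROI: origin corner and per-axis extent, in pixels."""

    origin: Tuple[int, ...]
    size: Tuple[int, ...]


@dataclass(frozen=True)
class Ellipse:
    """Ellipsoidal ROI: center and per-axis semi-axes, in pixels."""

    center: Tuple[float, ...]
    radii: Tuple[float, ...]


@dataclass(frozen=True)
class Perturbation:
    """Translate the truth by ``offset`` pixels (zero fill), then apply
    ``dilate`` dilation and ``erode`` erosion steps with the face-connected
    structuring element (4-connected in 2D)."""

    offset: Tuple[int, ...] = (0, 0)
    dilate: int = 0
    erode: int = 0


@dataclass(frozen=True)
class ScenarioSpec:
    """Parametric description of a synthetic prediction for a given truth."""

    name: str
    p: Optional[float] = None  # Bernoulli foreground probability (random)
    perturb: Optional[Perturbation] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ValueError(
                f"unknown scenario {self.name!r}; expected one of {SCENARIO_NAMES}"
            )
        if self.name == "random-segmentation":
            if self.p is None or not (0.0 <= self.p <= 1.0):
                raise ValueError(
                    "random-segmentation requires an explicit Bernoulli "
                    "probability p in [0, 1]"
                )
        if self.name == "perturbed" and self.perturb is None:
            raise ValueError("perturbed scenario requires a Perturbation spec")


RoiSpec = Union[Rectangle, Ellipse, int, float]


def _ratio_roi_count(n: int, ratio: float) -> int:
    """ROI pixel count realizing a background:ROI ratio as closely as possible.

    The ideal count is n / (R + 1); the nearer of its floor/ceil (>= 1) in
    achieved-ratio terms is used. Ratios whose ideal count rounds to zero
    (R > 2n - 1) are unachievable on the grid and raise.
    """
    if ratio < 0:
        raise ValueError("class ratio must be non-negative")
    ideal = n / (ratio + 1.0)
    if ideal < 0.5:
        raise ValueError(
            f"background:ROI ratio {ratio}:1 is unachievable on a grid of "
            f"{n} pixels (no integer ROI count >= 1 within tolerance)"
        )
    candidates = {max(1, int(np.floor(ideal))), min(n, int(np.ceil(ideal)))}
    return min(candidates, key=lambda k: (abs((n - k) / k - ratio), k))


def make_truth(
    shape: Sequence[int],
    roi_spec: RoiSpec,
    seed: int = 0,
) -> LabelMask:
    """Generate a binary ground truth (background 0, ROI 1).

    ``roi_spec`` is a :class:`Rectangle`, an :class:`Ellipse`, or a numeric
    target background:ROI ratio R. For a ratio, the ROI is a deterministic
    row-major prefix block whose pixel count makes the achieved ratio as
    close to R as integer quantization allows (remainder pixels go to
    background). ``seed`` is accepted for interface uniformity; truth
    geometry is fully deterministic.
    """
    shape = tuple(int(e) for e in shape)
    if any(e < 1 for e in shape):
        raise ValueError(f"degenerate shape {shape}")
    grid = np.zeros(shape, dtype=np.uint8)
    if isinstance(roi_spec, Rectangle):
        if len(roi_spec.origin) != len(shape) or len(roi_spec.size) != len(shape):
            raise ValueError("rectangle dimensionality does not match shape")
        slices = []
        for o, s, e in zip(roi_spec.origin, roi_spec.size, shape):
            if o < 0 or s < 1 or o + s > e:
                raise ValueError(
                    f"rectangle origin {roi_spec.origin} size {roi_spec.size} "
                    f"does not fit inside shape {shape}"
                )
            slices.append(slice(o, o + s))
        grid[tuple(slices)] = 1
    elif isinstance(roi_spec, Ellipse):
        if len(roi_spec.center) != len(shape) or len(roi_spec.radii) != len(shape):
            raise ValueError("ellipse dimensionality does not match shape")
        coords = np.indices(shape, dtype=float)
        dist2 = np.zeros(shape, dtype=float)
        for axis, (c, r) in enumerate(zip(roi_spec.center, roi_spec.radii)):
            if r <= 0:
                raise ValueError("ellipse radii must be positive")
            dist2 += ((coords[axis] - c) / r) ** 2
        inside = dist2 <= 1.0
        if not inside.any():
            raise ValueError("ellipse contains no pixel centers")
        grid[inside] = 1
    else:
        k = _ratio_roi_count(int(np.prod(shape)), float(roi_spec))
        flat = grid.reshape(-1)
        flat[:k] = 1
    return LabelMask(grid)


def class_ratio(mask: LabelMask, form: str = "background-to-roi") -> float:
    """Class-imbalance ratio of a binary truth mask.

    ``background-to-roi`` = (n - k)/k and ``total-to-roi`` = n/k, where k is
    the number of nonzero (ROI) pixels. An empty ROI has no ratio and raises.
    """
    values = mask.values if isinstance(mask, LabelMask) else np.asarray(mask)
    k = int(np.count_nonzero(values))
    if k == 0:
        raise ValueError("class ratio is undefined for an empty ROI")
    n = values.size
    if form == "background-to-roi":
        return (n - k) / k
    if form == "total-to-roi":
        return n / k
    raise ValueError(f"unknown ratio form {form!r}")


def _translate(mask: np.ndarray, offset: Sequence[int]) -> np.ndarray:
    """Shift a boolean grid by integer offsets with zero fill (no wrap)."""
    if len(offset) != mask.ndim:
        raise ValueError("offset dimensionality does not match mask")
    out = np.zeros_like(mask)
    src: List[slice] = []
    dst: List[slice] = []
    for o, e in zip(offset, mask.shape):
        if abs(o) >= e:
            return out  # shifted fully out of frame
        if o >= 0:
            src.append(slice(0, e - o))
            dst.append(slice(o, e))
        else:
            src.append(slice(-o, e))
            dst.append(slice(0, e + o))
    out[tuple(dst)] = mask[tuple(src)]
    return out


def predict_scenario(truth: LabelMask, spec: ScenarioSpec) -> LabelMask:
    """Generate the synthetic prediction a scenario describes for ``truth``."""
    shape = truth.shape
    if spec.name == "no-segmentation":
        pred = np.zeros(shape, dtype=np.uint8)
    elif spec.name == "full-segmentation":
        pred = np.ones(shape, dtype=np.uint8)
    elif spec.name == "random-segmentation":
        rng = np.random.default_rng(spec.seed)
        pred = (rng.random(shape) < spec.p).astype(np.uint8)
    else:  # perturbed
        assert spec.perturb is not None
        fg = _translate(truth.values > 0, spec.perturb.offset)
        structure = ndimage.generate_binary_structure(len(shape), 1)
        if spec.perturb.dilate > 0:
            fg = ndimage.binary_dilation(
                fg, structure=structure, iterations=spec.perturb.dilate
            )
        if spec.perturb.erode > 0:
            fg = ndimage.binary_erosion(
                fg, structure=structure, iterations=spec.perturb.erode,
                border_value=0,
            )
        pred = fg.astype(np.uint8)
    return LabelMask(pred)


def split_dataset(
    sample_ids: Sequence[str],
    fractions: Tuple[float, float, float] = (0.64, 0.16, 0.20),
    seed: int = 0,
) -> Tuple[List[str], List[str], List[str]]:
    """Seeded train/validation/test split of sample identifiers.

    Identifiers are shuffled with the seeded generator, then cut so that the
    validation and test partitions hold ``round(n * f)`` samples each and the
    training partition absorbs the rounding remainder. The default fractions
    are the common 64% / 16% / 20% experiment layout. Partitions are disjoint
    and their union is the input.
    """
    n = len(sample_ids)
    if n < 3:
        raise ValueError(f"need at least 3 samples to populate three partitions, got {n}")
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError("fractions must be three positive numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    shuffled = [sample_ids[i] for i in order]
    n_val = int(round(n * fractions[1]))
    n_test = int(round(n * fractions[2]))
    n_train = n - n_val - n_test
    if n_train < 1 or n_val < 1 or n_test < 1:
        raise ValueError(
            f"fractions {fractions} leave an empty partition at n={n}"
        )
    train = shuffled[:n_train]
    val = shuffled[n_train : n_train + n_val]
    test = shuffled[n_train + n_val :]
    return train, val, test
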