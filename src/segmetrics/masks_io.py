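"""Reading, writing and validating integer label masks.

Segmentation masks are exchanged as single-channel integer rasters (8/16-bit
grayscale PNG for 2D, single-channel TIFF for 2D or multi-page TIFF for 3D).
Pixel value = class label; 0 is always the background class. Binary 0/255
mask dialects are accepted only through the explicit :func:`coerce_binary`
reduction so that a 255-valued mask can never silently create 255 phantom
classes.

Score tables are round-trip-safe CSV or JSON; undefined metric values are
serialized as the literal ``"NA"``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "LabelMask",
    "ScoreRecord",
    "LabelSetWarning",
    "read_mask",
    "write_mask",
    "binarize",
    "coerce_binary",
    "validate_pair",
    "write_scores",
    "read_scores",
]

#: Marker for a metric value a documented edge policy declared undefined.
UNDEFINED = None

SCORE_COLUMNS = ("sample_id", "class_label", "metric", "value", "policy_note")


class MaskFormatError(ValueError):
    """Raised when a raster does not decode as a single-channel integer grid."""


class LabelSetWarning(UserWarning):
    """A prediction contains labels outside the configured label set."""


@dataclass(frozen=True)
class LabelMask:
    """An integer-valued 2D or 3D raster assigning one class per pixel.

    Parameters
    ----------
    values
        Integer array of shape ``(rows, cols)`` or ``(slices, rows, cols)``.
        All values must be >= 0.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim not in (2, 3):
            raise MaskFormatError(
                f"label mask must be 2D or 3D, got {arr.ndim}D shape {arr.shape}"
            )
        if not np.issubdtype(arr.dtype, np.integer):
            if np.issubdtype(arr.dtype, np.bool_):
                arr = arr.astype(np.uint8)
            else:
                raise MaskFormatError(
                    f"label mask requires an integer sample type, got {arr.dtype}"
                )
        if any(e < 1 for e in arr.shape):
            raise MaskFormatError(f"degenerate mask shape {arr.shape}")
        if arr.size and int(arr.min()) < 0:
            raise MaskFormatError("label masks cannot contain negative values")
        object.__setattr__(self, "values", arr)

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.values.shape

    @property
    def ndim(self) -> int:
        return self.values.ndim

    @property
    def labels(self) -> Tuple[int, ...]:
        """Sorted tuple of the distinct labels present."""
        return tuple(int(v) for v in np.unique(self.values))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabelMask):
            return NotImplemented
        return self.shape == other.shape and bool(
            np.array_equal(self.values, other.values)
        )

    def __hash__(self) -> int:  # frozen dataclass with array payload
        return hash((self.shape, self.values.tobytes()))


@dataclass
class ScoreRecord:
    """One metric value for a (sample, class) pair with policy provenance."""

    sample_id: str
    class_label: Union[int, str]  # an integer class or "all" for aggregates
    metric: str
    value: Optional[float]
    policy_note: str = ""


def _as_label_array(mask: Union[LabelMask, np.ndarray]) -> np.ndarray:
    return mask.values if isinstance(mask, LabelMask) else np.asarray(mask)


def read_mask(path: Union[str, Path], dialect: Optional[str] = None) -> LabelMask:
    """Read a single-channel integer raster as a :class:`LabelMask`.

    ``dialect`` is ``"label-png"`` or ``"label-tiff"``; inferred from the
    file suffix when omitted. PNG rasters must be 2D grayscale; TIFF rasters
    may additionally be 3D volumes stored as ``(slices, rows, cols)`` pages.
    Pixel values are taken verbatim — no remapping.
    """
    path = Path(path)
    if dialect is None:
        dialect = "label-tiff" if path.suffix.lower() in (".tif", ".tiff") else "label-png"
    if dialect not in ("label-png", "label-tiff"):
        raise ValueError(f"unknown mask dialect {dialect!r}")
    arr = iio.imread(path)
    max_ndim = 3 if dialect == "label-tiff" else 2
    if arr.ndim == max_ndim + 1 or (dialect == "label-png" and arr.ndim == 3):
        raise MaskFormatError(
            f"{path.name}: expected a single-channel raster, got "
            f"{arr.shape[-1]} channels (shape {arr.shape})"
        )
    if not np.issubdtype(arr.dtype, np.integer):
        raise MaskFormatError(
            f"{path.name}: non-integer sample type {arr.dtype}; "
            "label masks must be integer rasters"
        )
    return LabelMask(arr)


def write_mask(mask: LabelMask, path: Union[str, Path]) -> Path:
    """Write a :class:`LabelMask` in the label-raster dialect.

    2D masks go to PNG or single-page TIFF, 3D masks to multi-page TIFF.
    The narrowest unsigned dtype that holds the labels is used.
    """
    path = Path(path)
    arr = mask.values
    dtype = np.uint8 if (arr.size == 0 or int(arr.max()) < 256) else np.uint16
    out = arr.astype(dtype)
    if arr.ndim == 3 and path.suffix.lower() not in (".tif", ".tiff"):
        raise MaskFormatError("3D masks must be written as TIFF volumes")
    iio.imwrite(path, out)
    return path


def binarize(mask: Union[LabelMask, np.ndarray], label: int) -> np.ndarray:
    """One-vs-rest view: boolean grid, true exactly where ``mask == label``.

    The label need not be present; an absent label yields an all-false mask.
    """
    return _as_label_array(mask) == label


def coerce_binary(
    mask: Union[LabelMask, np.ndarray], threshold_rule: str = "nonzero-is-one"
) -> np.ndarray:
    """Reduce a 0/255-style binary mask dialect to a boolean grid.

    The only rule is ``nonzero-is-one``: any value > 0 is foreground.
    """
    if threshold_rule != "nonzero-is-one":
        raise ValueError(f"unknown threshold rule {threshold_rule!r}")
    return _as_label_array(mask) > 0


def validate_pair(
    truth: LabelMask,
    pred: LabelMask,
    labels: Optional[Iterable[int]] = None,
) -> Tuple[LabelMask, LabelMask]:
    """Check a ground-truth/prediction pair for shape agreement.

    Raises on shape mismatch. Labels present in the prediction but absent
    from the configured label set raise a :class:`LabelSetWarning` (models
    may emit classes the evaluation ignores) and are otherwise tolerated.
    Returns the pair unchanged.
    """
    if truth.shape != pred.shape:
        raise ValueError(
            f"shape mismatch: truth {truth.shape} vs prediction {pred.shape}"
        )
    if labels is not None:
        extra = set(pred.labels) - set(int(l) for l in labels)
        if extra:
            warnings.warn(
                f"prediction contains labels {sorted(extra)} outside the "
                f"configured label set; they are ignored by per-class scoring",
                LabelSetWarning,
                stacklevel=2,
            )
    return truth, pred


def _records_frame(records: Sequence[ScoreRecord]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": r.sample_id,
            "class_label": r.class_label,
            "metric": r.metric,
            "value": r.value,
            "policy_note": r.policy_note,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(SCORE_COLUMNS))


def write_scores(
    records: Sequence[ScoreRecord], path: Union[str, Path], format: str = "csv"
) -> Path:
    """Serialize score records to CSV or JSON.

    Undefined values become the literal ``NA``. The written file is
    round-trip safe through :func:`read_scores`.
    """
    if not records:
        raise ValueError("cannot write an empty score table")
    path = Path(path)
    if format == "csv":
        df = _records_frame(records)
        df.to_csv(path, index=False, na_rep="NA", float_format="%.17g")
    elif format == "json":
        payload = [
            {
                "sample_id": r.sample_id,
                "class_label": r.class_label,
                "metric": r.metric,
                "value": "NA" if r.value is None else r.value,
                "policy_note": r.policy_note,
            }
            for r in records
        ]
        path.write_text(json.dumps(payload, indent=1) + "\n")
    else:
        raise ValueError(f"unknown score format {format!r}")
    return path


def _coerce_class_label(raw: object) -> Union[int, str]:
    try:
        return int(raw)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        return str(raw)


def read_scores(path: Union[str, Path], format: Optional[str] = None) -> List[ScoreRecord]:
    """Read a score table written by :func:`write_scores`."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    records: List[ScoreRecord] = []
    if format == "csv":
        df = pd.read_csv(
            path, dtype=str, na_values=["NA"], keep_default_na=False
        )
        for row in df.itertuples(index=False):
            value = None if pd.isna(row.value) else float(row.value)
            note = "" if pd.isna(row.policy_note) else str(row.policy_note)
            records.append(
                ScoreRecord(
                    sample_id=str(row.sample_id),
                    class_label=_coerce_class_label(row.class_label),
                    metric=str(row.metric),
                    value=value,
                    policy_note=note,
                )
            )
    elif format == "json":
        for obj in json.loads(path.read_text()):
            value = obj["value"]
            records.append(
                ScoreRecord(
                    sample_id=str(obj["sample_id"]),
                    class_label=_coerce_class_label(obj["class_label"]),
                    metric=str(obj["metric"]),
                    value=None if value == "NA" else float(value),
                    policy_note=str(obj.get("policy_note", "")),
                )
            )
    else:
        raise ValueError(f"unknown score format {format!r}")
    return records
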