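"""Histological quantification: positivity counting, rubric scoring,
fusion index, and intensity/area quantification.

Implements the counting and scoring rules used for placental
immunohistochemistry: percent of syncytiotrophoblasts containing at least
one DAB-positive nucleus per counting field, a 9-level semi-quantitative
Ki67 proliferation rubric (0–4 in 0.5 steps), the trophoblast fusion
index of differentiating cytotrophoblast cultures, and area-fraction /
mean-intensity quantification of SA-β-gal and in situ zymography images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from skimage.filters import threshold_otsu

from .errors import ConfigError, DataError

__all__ = [
    "SyncytiaField",
    "IntensityImage",
    "FieldCountWarning",
    "percent_positive_syncytia",
    "aggregate_fields",
    "ki67_score",
    "KI67_RUBRIC",
    "fusion_index",
    "quantify_intensity",
    "group_fold_change",
    "FoldChange",
]


class FieldCountWarning(UserWarning):
    """Fewer counting fields than the study design calls for."""


@dataclass(frozen=True)
class SyncytiaField:
    """One microscope counting field.

    ``syncytia`` is a list of syncytiotrophoblast cells, each represented by
    the positivity flags (0/1) of its nuclei.
    """

    field_id: str
    syncytia: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        syncytia = tuple(tuple(int(f) for f in s) for s in self.syncytia)
        object.__setattr__(self, "syncytia", syncytia)
        if not syncytia:
            raise DataError(f"field {self.field_id!r}: no syncytia")
        for j, s in enumerate(syncytia):
            if not s:
                raise DataError(f"field {self.field_id!r}: syncytium {j} has no nuclei")
            if any(f not in (0, 1) for f in s):
                raise DataError(f"field {self.field_id!r}: non-binary positivity flag")

    @property
    def n_syncytia(self) -> int:
        return len(self.syncytia)

    @property
    def n_nuclei(self) -> int:
        return sum(len(s) for s in self.syncytia)


@dataclass(frozen=True)
class IntensityImage:
    """2-D staining/activity image with an optional tissue mask."""

    pixels: np.ndarray
    mask: np.ndarray | None = None
    channel: str = "SA-b-gal"

    def __post_init__(self) -> None:
        pixels = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", pixels)
        if pixels.ndim != 2:
            raise DataError("image must be a 2-D array")
        if not np.all(np.isfinite(pixels)) or np.any(pixels < 0):
            raise DataError("image intensities must be finite and non-negative")
        if self.mask is not None:
            mask = np.asarray(self.mask, dtype=bool)
            object.__setattr__(self, "mask", mask)
            if mask.shape != pixels.shape:
                raise DataError("mask shape does not match image shape")
            if not mask.any():
                raise DataError("tissue mask is empty")


def percent_positive_syncytia(field: SyncytiaField) -> float:
    """Percent of syncytia in the field containing >= 1 positive nucleus."""
    positive = sum(1 for s in field.syncytia if any(s))
    return 100.0 * positive / field.n_syncytia


def aggregate_fields(percentages: Sequence[float], min_fields: int = 12) -> tuple[float, float]:
    """Mean and SEM over counting fields.

    Emits :class:`FieldCountWarning` (not an error) when fewer than
    ``min_fields`` fields are supplied — the at-least-12-fields rule is a
    study-design guideline, not a mathematical precondition.
    """
    values = np.asarray(percentages, dtype=float)
    if values.size == 0:
        raise DataError("no counting fields supplied")
    if values.size < min_fields:
        warnings.warn(
            f"only {values.size} counting fields (< {min_fields})", FieldCountWarning,
            stacklevel=2,
        )
    mean = float(values.mean())
    sem = float(values.std(ddof=1) / np.sqrt(values.size)) if values.size > 1 else 0.0
    return mean, sem


# (upper edge, score) pairs for positive fractions; edges are exclusive on
# the right except the 0.75 seam, which belongs to 3.5 because only
# "more than 75%" is a strict bound in the rubric wording.
KI67_RUBRIC: tuple[tuple[float, float], ...] = (
    (0.05, 0.5),
    (0.10, 1.0),
    (0.25, 1.5),
    (0.33, 2.0),
    (0.50, 2.5),
    (0.66, 3.0),
    (0.75, 3.5),
)


def ki67_score(fraction_positive: float) -> float:
    """Semi-quantitative Ki67 proliferation score on the 0–4 rubric.

    Exactly zero positivity scores 0 (negative staining); any positive
    fraction below 5% scores 0.5; the remaining bins are left-closed /
    right-open up to 75%, with exactly 75% in the 3.5 bin and anything
    strictly above it scoring 4.
    """
    f = float(fraction_positive)
    if not 0.0 <= f <= 1.0:
        raise DataError(f"fraction_positive must lie in [0, 1], got {f}")
    if f == 0.0:
        return 0.0
    for upper, score in KI67_RUBRIC:
        if f < upper:
            return score
    if f == 0.75:
        return 3.5
    return 4.0


def fusion_index(
    nucleus_counts: Sequence[int],
    definition: Literal["nuclei", "cells"] = "nuclei",
) -> float:
    """Percent of trophoblast fusion in a field of counted cells.

    ``nucleus_counts`` holds the number of nuclei of every cell in the
    field. Two definitions are supported:

    * ``"nuclei"`` (default): percent of all nuclei residing in
      multinucleated (fused, >= 2 nuclei) cells;
    * ``"cells"``: percent of cells that are multinucleated.
    """
    counts = np.asarray(nucleus_counts, dtype=int)
    if counts.size == 0:
        raise DataError("no cells in field")
    if np.any(counts < 1):
        raise DataError("every cell must contain at least one nucleus")
    fused = counts >= 2
    if definition == "nuclei":
        return 100.0 * counts[fused].sum() / counts.sum()
    if definition == "cells":
        return 100.0 * fused.sum() / counts.size
    raise ConfigError(f"unknown fusion-index definition {definition!r}")


def quantify_intensity(
    image: IntensityImage,
    threshold: float | Literal["otsu"] = "otsu",
) -> tuple[float, float]:
    """Area fraction above threshold and mean intensity of a staining image.

    Statistics are restricted to the tissue mask when one is present. The
    default threshold is Otsu's method on the (masked) histogram; a fixed
    numeric threshold is accepted. A constant image has no Otsu threshold:
    the area fraction falls back to 0 with a warning.
    """
    pixels = image.pixels[image.mask] if image.mask is not None else image.pixels.ravel()
    mean_intensity = float(pixels.mean())
    if threshold == "otsu":
        if np.ptp(pixels) == 0:
            warnings.warn(
                "constant image: Otsu threshold undefined, area fraction set to 0",
                UserWarning, stacklevel=2,
            )
            return 0.0, mean_intensity
        thr = float(threshold_otsu(pixels))
    else:
        thr = float(threshold)
    area_fraction = float((pixels > thr).mean())
    return area_fraction, mean_intensity


@dataclass(frozen=True)
class FoldChange:
    """Group ratio with the field's x-fold reporting convention.

    ``fold`` is mean(A)/mean(B); ``magnitude`` is the reciprocal when the
    ratio is below 1 so that a drop reads as an "x-fold reduction".
    """

    fold: float
    magnitude: float
    direction: Literal["increase", "decrease", "none"]


def group_fold_change(group_a: Sequence[float], group_b: Sequence[float]) -> FoldChange:
    """Fold change between two groups of quantities (mean A over mean B)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("both groups must be non-empty")
    mean_b = b.mean()
    if mean_b == 0:
        raise DataError("reference group mean is zero")
    fold = float(a.mean() / mean_b)
    if fold == 1.0:
        return FoldChange(1.0, 1.0, "none")
    if fold < 1.0:
        return FoldChange(fold, 1.0 / fold, "decrease")
    return FoldChange(fold, fold, "increase")
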