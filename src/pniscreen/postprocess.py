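"""Probability-map post-processing: thresholding, component labeling, size filtering.

The screening pipeline scores each pixel 0/1 against a confidence threshold,
labels connected components per class, and discards very small foci (the
operating default removes components below 10,000 pixels, which suppresses the
dominant false-alarm mode of the segmenter without touching real structures).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage

from ._codes import CLASS_CHANNELS
from .segmentation import ProbabilityMap

__all__ = [
    "BinaryMask",
    "LabeledRegions",
    "binarize",
    "label_components",
    "filter_small",
]

#: Default small-focus cutoff in pixels (components strictly below are removed).
DEFAULT_MIN_AREA = 10_000


@dataclass
class BinaryMask:
    """A thresholded class mask plus the threshold that produced it."""

    values: np.ndarray  # bool, H x W
    class_name: str
    threshold_used: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("BinaryMask.values must be a 2-D raster")
        if self.class_name not in CLASS_CHANNELS:
            raise ValueError(f"unknown class {self.class_name!r}")
        if not 0.0 <= self.threshold_used <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")


@dataclass
class LabeledRegions:
    """Connected components of a binary class mask.

    ``labels`` uses 0 for background and consecutive integers 1..n for the
    components, numbered in raster-scan order of each component's first pixel.
    ``areas`` maps each label to its pixel count.
    """

    labels: np.ndarray  # int32, H x W
    areas: dict[int, int] = field(default_factory=dict)
    connectivity: int = 8

    @property
    def n_components(self) -> int:
        return len(self.areas)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def foreground(self) -> np.ndarray:
        return self.labels > 0

    def component(self, label: int) -> np.ndarray:
        if label not in self.areas:
            raise KeyError(f"no component with label {label}")
        return self.labels == label


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 8:
        return np.ones((3, 3), dtype=bool)
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    raise ValueError("connectivity must be 4 or 8")


def binarize(pmap: ProbabilityMap, class_name: str, threshold: float) -> BinaryMask:
    """Score pixels 0/1 against a confidence threshold.

    A pixel is included iff its confidence is >= ``threshold`` (ties at the
    threshold are included, so ``threshold=0`` selects every pixel).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    channel = CLASS_CHANNELS.get(class_name)
    if channel is None:
        raise ValueError(
            f"unknown class {class_name!r}; expected one of {sorted(CLASS_CHANNELS)}"
        )
    values = pmap.values[..., channel] >= threshold
    return BinaryMask(values=values, class_name=class_name, threshold_used=threshold)


def label_components(mask: BinaryMask | np.ndarray, connectivity: int = 8) -> LabeledRegions:
    """Label connected components and compute per-component pixel areas."""
    values = mask.values if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    if values.ndim != 2:
        raise ValueError("mask must be a 2-D raster")
    labels, n = ndimage.label(values, structure=_structure(connectivity))
    labels = labels.astype(np.int32, copy=False)
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    areas = {k: int(counts[k]) for k in range(1, n + 1)}
    return LabeledRegions(labels=labels, areas=areas, connectivity=connectivity)


def filter_small(regions: LabeledRegions, min_area: int = DEFAULT_MIN_AREA) -> LabeledRegions:
    """Remove components with area strictly below ``min_area``.

    Survivors are relabeled consecutively from 1, preserving the original
    raster-scan label order.
    """
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    keep = sorted(k for k, a in regions.areas.items() if a >= min_area)
    n_old = regions.n_components
    mapping = np.zeros(n_old + 1, dtype=np.int32)
    for new, old in enumerate(keep, start=1):
        mapping[old] = new
    labels = mapping[regions.labels]
    areas = {new: regions.areas[old] for new, old in enumerate(keep, start=1)}
    return LabeledRegions(labels=labels, areas=areas, connectivity=regions.connectivity)


def per_class_min_area(min_area: int | Mapping[str, int]) -> dict[str, int]:
    """Normalize a scalar or per-class mapping of size cutoffs."""
    if isinstance(min_area, Mapping):
        out = dict(min_area)
        for cls in CLASS_CHANNELS:
            out.setdefault(cls, DEFAULT_MIN_AREA)
        return out
    return {cls: int(min_area) for cls in CLASS_CHANNELS}
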