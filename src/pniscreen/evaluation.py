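"""Threshold-sweep segmentation metrics: IoU, detection rate, false-alarm rate.

Each metric is computed per class (tumor, nerve) as a function of the
confidence threshold, in two interpretations that are always reported side by
side because figure-caption-level metric definitions cannot adjudicate
between them:

* pixel mode — set arithmetic on pooled pixels: IoU = |P∩G|/|P∪G|,
  detection = |P∩G|/|G| (recall), false alarm = |P\\G|/|P| (false-discovery
  fraction);
* object mode — component counting: a ground-truth component is detected when
  at least a coverage fraction θ of its pixels is predicted; a predicted
  component is a false alarm when less than θ of it lies inside ground truth.

Aggregation pools raw counts over the image set before taking ratios, so
images with empty classes contribute without producing 0/0 terms.  Empty
denominators use IoU(∅,∅)=1, detection(no truth)=1, false-alarm(no
prediction)=0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._codes import CLASS_CHANNELS, CLASS_CODES
from .postprocess import BinaryMask, binarize, filter_small, label_components
from .segmentation import ProbabilityMap

__all__ = [
    "MetricCurve",
    "pixel_iou",
    "detection_rate",
    "false_alarm_rate",
    "sweep",
    "export_curves",
    "read_curves",
    "plot_curves",
]

METRICS = ("iou", "detection_rate", "false_alarm")
MODES = ("pixel", "object")


@dataclass
class MetricCurve:
    class_name: str
    metric: str
    thresholds: list[float]
    values: list[float]
    mode: str = "pixel"
    min_area_applied: int = 0

    def __post_init__(self) -> None:
        if len(self.thresholds) != len(self.values):
            raise ValueError("thresholds and values must align")
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly ascending")
        if self.metric not in METRICS or self.mode not in MODES:
            raise ValueError(f"unknown metric/mode {self.metric!r}/{self.mode!r}")


def _as_bool(mask: BinaryMask | np.ndarray) -> np.ndarray:
    values = mask.values if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    if values.ndim != 2:
        raise ValueError("expected a 2-D mask")
    return values


def _check_shapes(pred: np.ndarray, gt: np.ndarray) -> None:
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")


def pixel_iou(pred: BinaryMask | np.ndarray, gt: BinaryMask | np.ndarray) -> float:
    """Intersection over union of predicted and reference pixels (1.0 if both empty)."""
    p, g = _as_bool(pred), _as_bool(gt)
    _check_shapes(p, g)
    union = int((p | g).sum())
    if union == 0:
        return 1.0
    return int((p & g).sum()) / union


def _object_counts(
    subject: np.ndarray, reference: np.ndarray, coverage: float, connectivity: int = 8
) -> tuple[int, int]:
    """(components of subject with >= coverage of their pixels in reference, total)."""
    regions = label_components(subject, connectivity=connectivity)
    hit = 0
    for label, area in regions.areas.items():
        inside = int((reference[regions.labels == label]).sum())
        if inside / area >= coverage:
            hit += 1
    return hit, regions.n_components


def detection_rate(
    pred: BinaryMask | np.ndarray,
    gt: BinaryMask | np.ndarray,
    mode: str = "pixel",
    coverage: float = 0.5,
) -> float:
    """Fraction of reference material recovered by the prediction.

    pixel mode: recall |P∩G|/|G|.  object mode: fraction of ground-truth
    components with at least ``coverage`` of their pixels predicted.
    Returns 1.0 when there is no ground truth.
    """
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must lie in (0, 1]")
    p, g = _as_bool(pred), _as_bool(gt)
    _check_shapes(p, g)
    if mode == "pixel":
        total = int(g.sum())
        return int((p & g).sum()) / total if total else 1.0
    if mode == "object":
        hit, total = _object_counts(g, p, coverage)
        return hit / total if total else 1.0
    raise ValueError(f"unknown mode {mode!r}")


def false_alarm_rate(
    pred: BinaryMask | np.ndarray,
    gt: BinaryMask | np.ndarray,
    mode: str = "pixel",
    coverage: float = 0.5,
) -> float:
    """Fraction of predicted material not corresponding to the reference.

    pixel mode: |P\\G|/|P|.  object mode: fraction of predicted components
    with less than ``coverage`` of their pixels inside ground truth.
    Returns 0.0 when nothing is predicted.
    """
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must lie in (0, 1]")
    p, g = _as_bool(pred), _as_bool(gt)
    _check_shapes(p, g)
    if mode == "pixel":
        total = int(p.sum())
        return int((p & ~g).sum()) / total if total else 0.0
    if mode == "object":
        hit, total = _object_counts(p, g, coverage)
        return (total - hit) / total if total else 0.0
    raise ValueError(f"unknown mode {mode!r}")


def sweep(
    prob_maps: Sequence[ProbabilityMap],
    class_masks: Sequence[np.ndarray],
    thresholds: Sequence[float],
    min_area: int | Mapping[str, int] = 0,
    modes: Sequence[str] = MODES,
    connectivity: int = 8,
    coverage: float = 0.5,
) -> list[MetricCurve]:
    """Metric curves over an image set as a function of the threshold.

    Per threshold and class the pipeline's own post-processing is applied
    (binarize -> label -> small-focus filter); counts are pooled across the
    image set before ratio-taking.  ``class_masks`` are integer-coded
    ground-truth rasters.
    """
    if len(prob_maps) == 0:
        raise ValueError("empty image set")
    if len(prob_maps) != len(class_masks):
        raise ValueError("prob_maps and class_masks must align")
    thresholds = [float(t) for t in thresholds]
    if any(not 0.0 <= t <= 1.0 for t in thresholds):
        raise ValueError("thresholds must lie in [0, 1]")
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly ascending")
    areas = {cls: 0 for cls in CLASS_CHANNELS}
    if isinstance(min_area, Mapping):
        areas.update(min_area)
    else:
        areas = {cls: int(min_area) for cls in CLASS_CHANNELS}

    acc: dict[tuple[str, str, str], list[float]] = {
        (cls, metric, mode): []
        for cls in CLASS_CHANNELS
        for metric in METRICS
        for mode in modes
    }
    for thr in thresholds:
        for cls in CLASS_CHANNELS:
            inter = union = gt_total = pred_total = 0
            obj_gt_hit = obj_gt_total = obj_pred_hit = obj_pred_total = 0
            for pmap, gt_mask in zip(prob_maps, class_masks):
                gt = np.asarray(gt_mask) == CLASS_CODES[cls]
                pred_regions = filter_small(
                    label_components(binarize(pmap, cls, thr), connectivity=connectivity),
                    areas[cls],
                )
                pred = pred_regions.foreground()
                inter += int((pred & gt).sum())
                union += int((pred | gt).sum())
                gt_total += int(gt.sum())
                pred_total += int(pred.sum())
                if "object" in modes:
                    hit, total = _object_counts(gt, pred, coverage, connectivity)
                    obj_gt_hit += hit
                    obj_gt_total += total
                    hit, total = _object_counts(pred, gt, coverage, connectivity)
                    obj_pred_hit += hit
                    obj_pred_total += total
            if "pixel" in modes:
                acc[(cls, "iou", "pixel")].append(inter / union if union else 1.0)
                acc[(cls, "detection_rate", "pixel")].append(
                    inter / gt_total if gt_total else 1.0
                )
                acc[(cls, "false_alarm", "pixel")].append(
                    (pred_total - inter) / pred_total if pred_total else 0.0
                )
            if "object" in modes:
                acc[(cls, "iou", "object")].append(inter / union if union else 1.0)
                acc[(cls, "detection_rate", "object")].append(
                    obj_gt_hit / obj_gt_total if obj_gt_total else 1.0
                )
                acc[(cls, "false_alarm", "object")].append(
                    (obj_pred_total - obj_pred_hit) / obj_pred_total
                    if obj_pred_total
                    else 0.0
                )

    return [
        MetricCurve(
            class_name=cls,
            metric=metric,
            thresholds=list(thresholds),
            values=acc[(cls, metric, mode)],
            mode=mode,
            min_area_applied=areas[cls],
        )
        for cls in CLASS_CHANNELS
        for metric in METRICS
        for mode in modes
    ]


def export_curves(curves: Sequence[MetricCurve], path) -> None:
    """Write curves to CSV (class, metric, mode, threshold, value, min_area)."""
    rows = [
        {
            "class": c.class_name,
            "metric": c.metric,
            "mode": c.mode,
            "threshold": t,
            "value": v,
            "min_area": c.min_area_applied,
        }
        for c in curves
        for t, v in zip(c.thresholds, c.values)
    ]
    df = pd.DataFrame(rows, columns=["class", "metric", "mode", "threshold", "value", "min_area"])
    # %.17g keeps the round trip exact for float64 values
    df.to_csv(path, index=False, float_format="%.17g")


def read_curves(path) -> list[MetricCurve]:
    """Inverse of export_curves."""
    df = pd.read_csv(path, float_precision="round_trip")
    curves = []
    if df.empty:
        return curves
    for (cls, metric, mode, min_area), grp in df.groupby(
        ["class", "metric", "mode", "min_area"], sort=False
    ):
        grp = grp.sort_values("threshold")
        curves.append(
            MetricCurve(
                class_name=cls,
                metric=metric,
                thresholds=[float(t) for t in grp["threshold"]],
                values=[float(v) for v in grp["value"]],
                mode=mode,
                min_area_applied=int(min_area),
            )
        )
    return curves


def plot_curves(curves: Sequence[MetricCurve], path) -> None:
    """Render one panel per metric (classes overlaid), mirroring the usual
    threshold-sweep layout."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(METRICS), figsize=(4 * len(METRICS), 3.2))
    for ax, metric in zip(np.atleast_1d(axes), METRICS):
        for c in curves:
            if c.metric != metric:
                continue
            ax.plot(c.thresholds, c.values, label=f"{c.class_name} ({c.mode})")
        ax.set_xlabel("confidence threshold")
        ax.set_ylabel(metric)
        ax.set_ylim(-0.02, 1.02)
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)
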