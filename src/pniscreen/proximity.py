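"""Nerve-tumor spatial reasoning: pair distances, encirclement, candidate ranking.

This is the contextual half of the screening strategy: after nerve and tumor
have been detected independently, every (nerve component, tumor component)
pair is scored by the minimum Euclidean distance between their pixel centers,
close pairs become candidate fields, and the k closest fields per case are
presented for pathologist confirmation.  For pairs in contact, the fraction of
the nerve circumference hugged by tumor (encirclement) is measured as well,
since for intratumoral nerves at least a third of the circumference must be
involved to call invasion rather than focal abutment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .postprocess import BinaryMask, LabeledRegions

__all__ = [
    "Candidate",
    "RankingConfig",
    "component_min_distances",
    "measure_encirclement",
    "build_candidates",
    "suppress_overlaps",
    "rank_top_k",
    "crop_field",
]

#: Pixel-center distance at or below which two rasterized components are in
#: contact (adjacent pixels are 1 or sqrt(2) apart; true contact never
#: rasterizes to more than 2).
CONTACT_TOLERANCE_PX = 2.0

_STRUCT8 = np.ones((3, 3), dtype=bool)

PixelPair = tuple[tuple[int, int], tuple[int, int]]


@dataclass(frozen=True)
class Candidate:
    """One suspicious nerve/tumor pair with its presentation window."""

    slide_id: str
    nerve_id: int
    tumor_id: int
    min_distance: float
    closest_pair: PixelPair
    encirclement: float
    field_window: tuple[int, int, int, int]  # row0, col0, height, width
    nerve_area: int
    tumor_area: int


@dataclass(frozen=True)
class RankingConfig:
    """How candidates are filtered, deduplicated, and presented.

    ``k`` fields are shown per case (40 by default; 20 for tumor-only cases,
    mirroring the clinical protocol).  Pairs farther apart than
    ``max_distance`` pixels are never candidates.
    """

    k: int = 40
    k_tumor_only: int = 20
    max_distance: float = 100.0
    field_size: int = 512
    overlap_suppression: float = 0.5

    def __post_init__(self) -> None:
        if self.k < 1 or self.k_tumor_only < 1:
            raise ValueError("k must be >= 1")
        if self.max_distance < 0:
            raise ValueError("max_distance must be >= 0")
        if self.field_size < 1:
            raise ValueError("field_size must be >= 1")


def _sort_key(c: Candidate):
    return (
        c.min_distance,
        -(c.nerve_area + c.tumor_area),
        c.slide_id,
        c.field_window[0],
        c.field_window[1],
    )


def component_min_distances(
    nerve: LabeledRegions,
    tumor: LabeledRegions,
    max_distance: float | None = None,
) -> list[tuple[int, int, float, PixelPair]]:
    """Exact minimum pixel-center distance for every nerve/tumor pair.

    For each nerve component an exact Euclidean distance transform is taken
    and sampled at every tumor pixel; the per-tumor-component minimum equals
    the brute-force minimum over all pixel pairs.  Overlapping components have
    distance 0.  Pairs beyond ``max_distance`` are omitted when it is given.
    """
    if nerve.shape != tumor.shape:
        raise ValueError(f"raster shapes differ: {nerve.shape} vs {tumor.shape}")
    out: list[tuple[int, int, float, PixelPair]] = []
    if not nerve.areas or not tumor.areas:
        return out
    t_rows, t_cols = np.nonzero(tumor.labels)
    t_labels = tumor.labels[t_rows, t_cols]
    for nid in sorted(nerve.areas):
        comp = nerve.labels == nid
        dist, idx = ndimage.distance_transform_edt(~comp, return_indices=True)
        d_at_tumor = dist[t_rows, t_cols]
        for tid in sorted(tumor.areas):
            sel = np.flatnonzero(t_labels == tid)
            j = sel[np.argmin(d_at_tumor[sel])]
            d = float(d_at_tumor[j])
            if max_distance is not None and d > max_distance:
                continue
            tr, tc = int(t_rows[j]), int(t_cols[j])
            nr, nc = int(idx[0, tr, tc]), int(idx[1, tr, tc])
            out.append((nid, tid, d, ((nr, nc), (tr, tc))))
    return out


def component_boundary(comp: np.ndarray) -> np.ndarray:
    """Component pixels 8-adjacent to any non-component pixel (or the raster edge)."""
    eroded = ndimage.binary_erosion(comp, structure=_STRUCT8, border_value=0)
    return comp & ~eroded


def measure_encirclement(
    nerve_id: int,
    nerve: LabeledRegions,
    tumor_mask: BinaryMask | np.ndarray,
    epsilon: float = 3.0,
) -> float:
    """Fraction of a nerve component's boundary lying within epsilon of tumor."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    comp = nerve.component(nerve_id)
    tumor = tumor_mask.values if isinstance(tumor_mask, BinaryMask) else np.asarray(tumor_mask, dtype=bool)
    if tumor.shape != comp.shape:
        raise ValueError("tumor mask shape differs from nerve raster")
    boundary = component_boundary(comp)
    n_boundary = int(boundary.sum())
    if n_boundary == 0 or not tumor.any():
        return 0.0
    dist = ndimage.distance_transform_edt(~tumor)
    return float(np.count_nonzero(dist[boundary] <= epsilon)) / n_boundary


def _clamp_window(
    center: tuple[float, float], field_size: int, shape: tuple[int, int]
) -> tuple[int, int, int, int]:
    h, w = shape
    fh, fw = min(field_size, h), min(field_size, w)
    r0 = int(round(center[0] - fh / 2))
    c0 = int(round(center[1] - fw / 2))
    r0 = max(0, min(r0, h - fh))
    c0 = max(0, min(c0, w - fw))
    return r0, c0, fh, fw


def build_candidates(
    pairs: Sequence[tuple[int, int, float, PixelPair]],
    nerve: LabeledRegions,
    tumor: LabeledRegions,
    tumor_mask: BinaryMask | np.ndarray,
    config: RankingConfig = RankingConfig(),
    slide_id: str = "slide",
    encirclement_epsilon: float = 3.0,
) -> list[Candidate]:
    """Turn surviving distance pairs into presentable candidate fields.

    Encirclement is measured only for pairs in rasterized contact
    (distance <= 2 px); separated pairs get encirclement 0.  The field window
    is centered on the closest pixel pair and clamped to the slide bounds.
    """
    out = []
    for nid, tid, d, pair in pairs:
        if d > config.max_distance:
            continue
        if d <= CONTACT_TOLERANCE_PX:
            enc = measure_encirclement(nid, nerve, tumor_mask, epsilon=encirclement_epsilon)
        else:
            enc = 0.0
        (nr, nc), (tr, tc) = pair
        center = ((nr + tr) / 2.0, (nc + tc) / 2.0)
        window = _clamp_window(center, config.field_size, nerve.shape)
        out.append(
            Candidate(
                slide_id=slide_id,
                nerve_id=nid,
                tumor_id=tid,
                min_distance=float(d),
                closest_pair=pair,
                encirclement=float(enc),
                field_window=window,
                nerve_area=nerve.areas[nid],
                tumor_area=tumor.areas[tid],
            )
        )
    return out


def _window_iou(a: tuple[int, int, int, int], b: tuple[int, int, int, int]) -> float:
    ar0, ac0, ah, aw = a
    br0, bc0, bh, bw = b
    ih = max(0, min(ar0 + ah, br0 + bh) - max(ar0, br0))
    iw = max(0, min(ac0 + aw, bc0 + bw) - max(ac0, bc0))
    inter = ih * iw
    union = ah * aw + bh * bw - inter
    return inter / union if union else 0.0


def suppress_overlaps(
    candidates: Sequence[Candidate], iou_threshold: float = 0.5
) -> list[Candidate]:
    """Greedy dedup: keep the closest pair, drop later fields whose window
    IoU with any kept field exceeds the threshold."""
    kept: list[Candidate] = []
    for cand in sorted(candidates, key=_sort_key):
        if all(_window_iou(cand.field_window, k.field_window) <= iou_threshold for k in kept):
            kept.append(cand)
    return kept


def rank_top_k(candidates: Sequence[Candidate], k: int) -> list[Candidate]:
    """The k most suspicious fields of a case, closest nerve-tumor pairs first.

    Ties on distance are broken by larger combined component area, then by
    (slide_id, row, col), so the ordering is invariant to input permutation.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    return sorted(candidates, key=_sort_key)[:k]


def crop_field(tile: np.ndarray, candidate: Candidate) -> tuple[np.ndarray, tuple[int, int, int, int]]:
    """Pixel-exact crop of a candidate's field window."""
    r0, c0, h, w = candidate.field_window
    th, tw = tile.shape[:2]
    if h <= 0 or w <= 0 or r0 < 0 or c0 < 0 or r0 + h > th or c0 + w > tw:
        raise ValueError(f"degenerate or out-of-bounds window {candidate.field_window}")
    return tile[r0 : r0 + h, c0 : c0 + w].copy(), candidate.field_window
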