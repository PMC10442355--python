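"""Independent brute-force oracles used to cross-check the pipeline math.

Everything here is deliberately naive (pure-Python flood fill, all-pairs
pixel distances, direct set arithmetic) so it shares no code path with the
implementations it verifies.
"""

from __future__ import annotations

import numpy as np


def flood_fill_components(mask: np.ndarray, connectivity: int = 8) -> list[set[tuple[int, int]]]:
    """Connected components by BFS flood fill, in raster-scan discovery order."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    seen = np.zeros_like(mask)
    comps = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c] or seen[r, c]:
                continue
            comp = set()
            stack = [(r, c)]
            seen[r, c] = True
            while stack:
                pr, pc = stack.pop()
                comp.add((pr, pc))
                for dr, dc in nbrs:
                    nr, nc = pr + dr, pc + dc
                    if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and not seen[nr, nc]:
                        seen[nr, nc] = True
                        stack.append((nr, nc))
            comps.append(comp)
    return comps


def all_pairs_min_distance(pixels_a: np.ndarray, pixels_b: np.ndarray) -> float:
    """Exhaustive minimum Euclidean distance between two pixel sets.

    Chunked over the first set so large components stay within memory.
    """
    a = np.argwhere(pixels_a).astype(float)
    b = np.argwhere(pixels_b).astype(float)
    best = np.inf
    for i in range(0, len(a), 128):
        chunk = a[i : i + 128]
        d2 = ((chunk[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
        best = min(best, float(d2.min()))
    return float(np.sqrt(best))


def iou(pred: np.ndarray, gt: np.ndarray) -> float:
    p = {tuple(x) for x in np.argwhere(pred)}
    g = {tuple(x) for x in np.argwhere(gt)}
    if not p and not g:
        return 1.0
    return len(p & g) / len(p | g)


def detection_pixel(pred: np.ndarray, gt: np.ndarray) -> float:
    p = {tuple(x) for x in np.argwhere(pred)}
    g = {tuple(x) for x in np.argwhere(gt)}
    return len(p & g) / len(g) if g else 1.0


def false_alarm_pixel(pred: np.ndarray, gt: np.ndarray) -> float:
    p = {tuple(x) for x in np.argwhere(pred)}
    g = {tuple(x) for x in np.argwhere(gt)}
    return len(p - g) / len(p) if p else 0.0


def detection_object(pred: np.ndarray, gt: np.ndarray, coverage: float = 0.5) -> float:
    comps = flood_fill_components(gt, connectivity=8)
    if not comps:
        return 1.0
    p = {tuple(x) for x in np.argwhere(pred)}
    hit = sum(1 for comp in comps if len(comp & p) / len(comp) >= coverage)
    return hit / len(comps)


def false_alarm_object(pred: np.ndarray, gt: np.ndarray, coverage: float = 0.5) -> float:
    comps = flood_fill_components(pred, connectivity=8)
    if not comps:
        return 0.0
    g = {tuple(x) for x in np.argwhere(gt)}
    false = sum(1 for comp in comps if len(comp & g) / len(comp) < coverage)
    return false / len(comps)


def boundary_pixels(comp: np.ndarray) -> np.ndarray:
    """Component pixels with any 8-neighbor (or the raster edge) outside."""
    comp = np.asarray(comp, dtype=bool)
    h, w = comp.shape
    out = np.zeros_like(comp)
    for r, c in np.argwhere(comp):
        edge = False
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                nr, nc = r + dr, c + dc
                if not (0 <= nr < h and 0 <= nc < w) or not comp[nr, nc]:
                    edge = True
        out[r, c] = edge
    return out


def encirclement(comp: np.ndarray, tumor: np.ndarray, epsilon: float = 3.0) -> float:
    """Fraction of boundary pixels within epsilon of any tumor pixel."""
    boundary = np.argwhere(boundary_pixels(comp)).astype(float)
    t = np.argwhere(tumor).astype(float)
    if boundary.size == 0 or t.size == 0:
        return 0.0
    covered = 0
    for i in range(0, len(boundary), 128):
        chunk = boundary[i : i + 128]
        d2 = ((chunk[:, None, :] - t[None, :, :]) ** 2).sum(axis=2)
        covered += int((np.sqrt(d2.min(axis=1)) <= epsilon).sum())
    return covered / len(boundary)


def random_blob_mask(rng: np.random.Generator, shape: tuple[int, int], p: float = 0.35) -> np.ndarray:
    """Random clumpy mask: Bernoulli noise smoothed by majority of a cross."""
    raw = rng.random(shape) < p
    padded = np.pad(raw, 1)
    score = (
        padded[1:-1, 1:-1].astype(int)
        + padded[:-2, 1:-1]
        + padded[2:, 1:-1]
        + padded[1:-1, :-2]
        + padded[1:-1, 2:]
    )
    return score >= 3
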