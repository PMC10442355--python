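"""Seeded synthetic H&E-like tiles, ground truth, and multi-slide case studies.

The generator emulates the structure of a pancreatic-cancer screening study:
desk-scale RGB tiles stand in for scanned slides, each containing wavy nerve
bundles, lobulated malignant gland clusters, regular benign-gland confounders,
and optionally planted perineural-invasion (PNI) events with controlled
nerve-tumor distance and encirclement fraction.  Cases bundle many slides with
slide counts drawn from the clinical study's distributions (27 +/- 9.4 slides
per full case, 6.1 +/- 1.8 for tumor-only cases), and studies mix PNI-positive
and negative cases at a configurable prevalence.

Geometric ground rules (free choices of this package, exposed in TileSpec):

* structures are large enough that real nerves and tumor clusters always
  survive the pipeline's 10,000-pixel small-focus filter at default settings;
* benign glands never come within 50 px of a nerve (benign glands do not
  appear in very close proximity to nerves, which is exactly why the
  proximity step tolerates their misclassification as tumor);
* non-event tumor keeps a >= 8 px gap from every nerve, so the only true
  nerve-tumor contacts in a scene are the planted events.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.stats import truncnorm

from ._codes import BACKGROUND, BENIGN_GLAND, MASK_CODES, NERVE, TUMOR
from .postprocess import label_components
from .proximity import measure_encirclement

__all__ = [
    "TileSpec",
    "PNIEvent",
    "GroundTruth",
    "CaseSpec",
    "SyntheticCase",
    "PlacementError",
    "generate_tile",
    "render_tile",
    "generate_case",
    "generate_study",
    "study_case_specs",
]

# placement clearances, in pixels
_NERVE_NERVE_GAP = 10.0
_TUMOR_NERVE_GAP = 8.0
_TUMOR_TUMOR_GAP = 4.0
_BENIGN_NERVE_GAP = 50.0
_BAND_WIDTH = 14.0  # radial thickness of the tumor collar in encirclement events
_BENIGN_RADIUS = (20.0, 35.0)

_EVENT_DISTANCE_TOL = 2.0
_EVENT_ENCIRCLEMENT_TOL = 0.1


class PlacementError(RuntimeError):
    """Raised when a structure or event cannot be placed after bounded retries."""


@dataclass(frozen=True)
class TileSpec:
    """Geometry and appearance parameters of one synthetic tile."""

    height: int = 512
    width: int = 512
    n_nerves: int = 2
    n_malignant_glands: int = 2
    n_benign_glands: int = 2
    nerve_thickness_range: tuple[float, float] = (26.0, 36.0)
    gland_radius_range: tuple[float, float] = (78.0, 95.0)
    background_noise_sd: float = 6.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 64 or self.width < 64:
            raise ValueError("tiles must be at least 64 x 64")
        if min(self.n_nerves, self.n_malignant_glands, self.n_benign_glands) < 0:
            raise ValueError("structure counts must be >= 0")
        for name in ("nerve_thickness_range", "gland_radius_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must satisfy 0 < lo <= hi")


@dataclass(frozen=True)
class PNIEvent:
    """A planted nerve-tumor interaction.

    ``target_distance`` is the intended minimum pixel-center distance (0 means
    contact); ``target_encirclement`` the intended fraction of the nerve
    circumference hugged by tumor.  Component labels are filled in by the
    generator once the tile is rasterized and verified.
    """

    target_distance: float = 0.0
    target_encirclement: float = 0.5
    inside_tumor_body: bool = False
    nerve_id: int | None = None
    tumor_id: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_encirclement <= 1.0:
            raise ValueError("target_encirclement must lie in [0, 1]")
        if self.target_distance < 0:
            raise ValueError("target_distance must be >= 0")
        if self.target_encirclement > 0 and self.target_distance != 0:
            raise ValueError("encircling tumor implies contact (target_distance 0)")


@dataclass
class GroundTruth:
    """Integer-coded class mask plus the planted events (the annotation analogue)."""

    class_mask: np.ndarray  # uint8, codes 0..3
    events: list[PNIEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.class_mask = np.asarray(self.class_mask, dtype=np.uint8)
        if self.class_mask.ndim != 2:
            raise ValueError("class_mask must be 2-D")
        if not np.isin(self.class_mask, MASK_CODES).all():
            raise ValueError("class_mask contains codes outside 0..3")

    def class_bool(self, code: int) -> np.ndarray:
        return self.class_mask == code


@dataclass(frozen=True)
class CaseSpec:
    """One case of the simulated study.

    When ``n_slides`` is None it is drawn from a truncated normal with the
    study's per-case slide statistics (tumor-only cases use the smaller
    tumor-slide distribution).
    """

    case_id: str
    pni_positive: bool = False
    tumor_only: bool = False
    n_events: int = 0
    n_slides: int | None = None
    slides_mean: float = 27.0
    slides_sd: float = 9.4
    tumor_only_mean: float = 6.1
    tumor_only_sd: float = 1.8

    def __post_init__(self) -> None:
        if self.n_slides is not None and self.n_slides < 1:
            raise ValueError("n_slides must be >= 1")
        if self.pni_positive != (self.n_events >= 1):
            raise ValueError("n_events >= 1 iff pni_positive")


@dataclass
class SyntheticCase:
    spec: CaseSpec
    slides: list[tuple[np.ndarray | None, GroundTruth]]

    @property
    def n_events(self) -> int:
        return sum(len(gt.events) for _, gt in self.slides)


# ---------------------------------------------------------------------------
# geometry primitives


def _wavy_path(
    rng: np.random.Generator,
    shape: tuple[int, int],
    margin: float,
    length: float,
    step: float = 2.0,
) -> np.ndarray:
    """A smooth random-walk polyline bouncing off the tile borders."""
    h, w = shape
    pos = np.array(
        [rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)], dtype=float
    )
    heading = rng.uniform(0.0, 2 * np.pi)
    curvature = 0.0
    pts = [pos.copy()]
    for _ in range(int(length / step)):
        curvature = 0.95 * curvature + rng.normal(0.0, 0.012)
        heading += curvature
        delta = step * np.array([np.sin(heading), np.cos(heading)])
        nxt = pos + delta
        if not margin <= nxt[0] <= h - margin:
            heading = -heading
            curvature = 0.0
            nxt = pos + step * np.array([np.sin(heading), np.cos(heading)])
        if not margin <= nxt[1] <= w - margin:
            heading = np.pi - heading
            curvature = 0.0
            nxt = pos + step * np.array([np.sin(heading), np.cos(heading)])
        pos = np.clip(nxt, [margin, margin], [h - margin, w - margin])
        pts.append(pos.copy())
    return np.asarray(pts)


def _disk_offsets(radius: float) -> np.ndarray:
    r = int(np.floor(radius))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dy**2 + dx**2 <= radius**2
    return np.stack([dy[keep], dx[keep]], axis=1)


def _stamp_path(pts: np.ndarray, radius: float, shape: tuple[int, int]) -> np.ndarray:
    """Union of disks of ``radius`` centered on the (rounded) polyline points.

    Equivalent to thresholding the point distance map at ``radius`` but far
    cheaper for repeated placement attempts.
    """
    h, w = shape
    centers = np.round(pts).astype(np.int64)
    px = centers[:, None, :] + _disk_offsets(radius)[None, :, :]
    px = px.reshape(-1, 2)
    np.clip(px[:, 0], 0, h - 1, out=px[:, 0])
    np.clip(px[:, 1], 0, w - 1, out=px[:, 1])
    raster = np.zeros(h * w, dtype=bool)
    raster[px[:, 0] * w + px[:, 1]] = True
    return raster.reshape(h, w)


def _sample_lobes(
    rng: np.random.Generator, radius: float, n_lobes: int = 9
) -> list[tuple[float, float, float]]:
    """Lobe offsets (dy, dx, radius) for a lobulated gland cluster."""
    lobes = []
    for _ in range(n_lobes):
        ang = rng.uniform(0, 2 * np.pi)
        off = rng.uniform(0.45, 0.85) * radius
        lr = rng.uniform(0.28, 0.4) * radius
        lobes.append((off * np.sin(ang), off * np.cos(ang), lr))
    return lobes


def _raster_cluster(
    center: np.ndarray,
    base_r: float,
    lobes: Sequence[tuple[float, float, float]],
    shape: tuple[int, int],
) -> np.ndarray:
    h, w = shape
    reach = base_r + max((abs(dy) + abs(dx) + lr for dy, dx, lr in lobes), default=0.0)
    r0 = max(int(center[0] - reach) - 1, 0)
    r1 = min(int(center[0] + reach) + 2, h)
    c0 = max(int(center[1] - reach) - 1, 0)
    c1 = min(int(center[1] + reach) + 2, w)
    blob = np.zeros(shape, dtype=bool)
    if r0 >= r1 or c0 >= c1:
        return blob
    rr, cc = np.ogrid[r0:r1, c0:c1]
    local = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= base_r**2
    for dy, dx, lr in lobes:
        local |= (rr - (center[0] + dy)) ** 2 + (cc - (center[1] + dx)) ** 2 <= lr**2
    blob[r0:r1, c0:c1] = local
    return blob


def _gland_cluster(
    rng: np.random.Generator,
    center: np.ndarray,
    radius: float,
    shape: tuple[int, int],
) -> np.ndarray:
    """A lobulated malignant-gland cluster: base disk plus overlapping lobes."""
    return _raster_cluster(center, 0.8 * radius, _sample_lobes(rng, radius), shape)


def _disk(center: np.ndarray, radius: float, shape: tuple[int, int]) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


# ---------------------------------------------------------------------------
# tile generation


class _Scene:
    """Mutable painting state for one generation attempt.

    Keeps exact distance maps to the already-painted nerve and tumor pixels
    (refreshed once per accepted structure), so placement retries only need
    to sample them instead of recomputing distance transforms.
    """

    def __init__(self, shape: tuple[int, int]):
        self.shape = shape
        self.nerve = np.zeros(shape, dtype=bool)
        self.tumor = np.zeros(shape, dtype=bool)
        self.benign = np.zeros(shape, dtype=bool)
        self.dist_nerve = np.full(shape, np.inf)
        self.dist_tumor = np.full(shape, np.inf)

    def add_nerve(self, ribbon: np.ndarray) -> None:
        self.nerve |= ribbon
        np.minimum(self.dist_nerve, ndimage.distance_transform_edt(~ribbon), out=self.dist_nerve)

    def add_tumor(self, piece: np.ndarray) -> None:
        self.tumor |= piece
        np.minimum(self.dist_tumor, ndimage.distance_transform_edt(~piece), out=self.dist_tumor)

    def gap_to_nerve(self, new: np.ndarray) -> float:
        return float(self.dist_nerve[new].min()) if new.any() else np.inf

    def gap_to_tumor(self, new: np.ndarray) -> float:
        return float(self.dist_tumor[new].min()) if new.any() else np.inf

    def class_mask(self) -> np.ndarray:
        mask = np.zeros(self.shape, dtype=np.uint8)
        mask[self.nerve] = NERVE
        mask[self.tumor & ~self.nerve] = TUMOR
        mask[self.benign & (mask == BACKGROUND)] = BENIGN_GLAND
        return mask


def _place_nerve(
    scene: _Scene, rng: np.random.Generator, spec: TileSpec, retries: int = 60
) -> tuple[np.ndarray, float] | None:
    """Paint one nerve ribbon; returns (path points, radius) or None."""
    for _ in range(retries):
        drawn = _draw_ribbon(scene, rng, spec)
        if drawn is None:
            continue
        pts, radius, ribbon = drawn
        scene.add_nerve(ribbon)
        return pts, radius
    return None


def _draw_ribbon(
    scene: _Scene, rng: np.random.Generator, spec: TileSpec
) -> tuple[np.ndarray, float, np.ndarray] | None:
    """One nerve-ribbon attempt honoring all clearances (scene not modified)."""
    h, w = scene.shape
    scale = min(h, w) / 512.0
    thickness = rng.uniform(*spec.nerve_thickness_range)
    radius = thickness / 2.0
    length = rng.uniform(460, 620) * scale
    pts = _wavy_path(rng, scene.shape, margin=radius + 4, length=length)
    # sound quick reject: every ribbon pixel is within `radius` of a path
    # point, so a path point closer than radius+gap to painted tissue
    # already violates the clearance
    ri = np.round(pts).astype(int)
    if scene.dist_nerve[ri[:, 0], ri[:, 1]].min() < radius + _NERVE_NERVE_GAP:
        return None
    if scene.dist_tumor[ri[:, 0], ri[:, 1]].min() < radius + _TUMOR_NERVE_GAP:
        return None
    ribbon = _stamp_path(pts, radius, scene.shape)
    if ribbon.sum() < 0.85 * length * thickness:
        return None  # path folded over itself; ribbon thinner than intended
    if scene.gap_to_nerve(ribbon) < _NERVE_NERVE_GAP:
        return None
    if scene.gap_to_tumor(ribbon) < _TUMOR_NERVE_GAP:
        return None
    return pts, radius, ribbon


def _place_cluster(
    scene: _Scene, rng: np.random.Generator, spec: TileSpec, retries: int = 60
) -> bool:
    h, w = scene.shape
    for _ in range(retries):
        radius = rng.uniform(*spec.gland_radius_range)
        if 2.6 * radius >= min(h, w):
            radius = min(h, w) / 2.8
        base_r = 0.8 * radius
        # clusters may clip the tile border (tissue does not stop at a scan
        # window), so only half the base disk must fit
        margin = 0.5 * base_r
        ci = np.array([rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)])
        # sound quick reject: the cluster contains the base disk around ci
        ci_int = np.clip(np.round(ci).astype(int), 0, [h - 1, w - 1])
        if scene.dist_nerve[ci_int[0], ci_int[1]] < base_r + _TUMOR_NERVE_GAP:
            continue
        if scene.dist_tumor[ci_int[0], ci_int[1]] < base_r + _TUMOR_TUMOR_GAP:
            continue
        blob = _gland_cluster(rng, ci, radius, scene.shape)
        if scene.gap_to_nerve(blob) < _TUMOR_NERVE_GAP:
            continue
        if scene.gap_to_tumor(blob) < _TUMOR_TUMOR_GAP:
            continue
        scene.add_tumor(blob)
        return True
    return False


def _place_benign(
    scene: _Scene, rng: np.random.Generator, spec: TileSpec, retries: int = 60
) -> bool:
    h, w = scene.shape
    # benign geometry scales with the tile so small test tiles stay placeable;
    # the nerve clearance never drops below 12 px (well clear of the contact
    # tolerance and the encirclement epsilon)
    scale = min(h, w) / 512.0
    nerve_gap = max(_BENIGN_NERVE_GAP * scale, 12.0)
    for _ in range(retries):
        radius = rng.uniform(*_BENIGN_RADIUS) * max(scale, 0.3)
        margin = radius + 2
        center = np.array(
            [rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)]
        )
        ci = np.clip(np.round(center).astype(int), 0, [h - 1, w - 1])
        if scene.dist_nerve[ci[0], ci[1]] < radius + nerve_gap:
            continue
        disk = _disk(center, radius, scene.shape)
        if scene.gap_to_nerve(disk) < nerve_gap:
            continue
        if scene.gap_to_tumor(disk) < 2.0:
            continue
        if (disk & scene.benign).any():
            continue
        scene.benign |= disk
        return True
    return False


def _normal_at(pts: np.ndarray, i: int) -> np.ndarray:
    j0, j1 = max(i - 2, 0), min(i + 2, len(pts) - 1)
    tangent = pts[j1] - pts[j0]
    norm = np.array([-tangent[1], tangent[0]])
    n = np.linalg.norm(norm)
    return norm / n if n > 0 else np.array([1.0, 0.0])


def _place_event(
    scene: _Scene,
    rng: np.random.Generator,
    spec: TileSpec,
    event: PNIEvent,
    retries: int = 30,
) -> tuple[tuple[int, int], tuple[int, int]] | None:
    """Paint one event's nerve and tumor; returns seed pixels (nerve, tumor)."""
    for _ in range(retries):
        drawn = _draw_ribbon(scene, rng, spec)
        if drawn is None:
            continue
        pts, radius, ribbon = drawn
        ribbon_edt = ndimage.distance_transform_edt(~ribbon)
        built = _build_event_tumor(scene, rng, spec, event, pts, radius, ribbon, ribbon_edt)
        if built is None:
            continue
        piece, body = built
        # pre-verify the event geometry before committing the scene, so a bad
        # draw costs one retry here instead of a whole-tile regeneration
        d = float(ribbon_edt[piece].min())
        if abs(d - event.target_distance) > _EVENT_DISTANCE_TOL:
            continue
        enc = _local_encirclement(ribbon, piece)
        if abs(enc - event.target_encirclement) > 0.8 * _EVENT_ENCIRCLEMENT_TOL:
            continue
        scene.add_nerve(ribbon)
        scene.add_tumor(piece)
        mid = pts[len(pts) // 2]
        nerve_seed = (int(round(mid[0])), int(round(mid[1])))
        # seed inside the tumor *body*: the collar may shed a small strip on
        # the far side of the nerve, which must not become the event's
        # recorded component
        core = body & piece
        if not core.any():
            core = piece
        labels, n = ndimage.label(core, structure=np.ones((3, 3)))
        if n > 1:  # seed the largest fragment of the body
            counts = np.bincount(labels.ravel())
            counts[0] = 0
            core = labels == counts.argmax()
        trows, tcols = np.nonzero(core)
        tumor_seed = (int(trows[0]), int(tcols[0]))
        return nerve_seed, tumor_seed
    return None


def _local_encirclement(ribbon: np.ndarray, piece: np.ndarray, epsilon: float = 3.0) -> float:
    """Fraction of the ribbon boundary within epsilon of the tumor piece."""
    eroded = ndimage.binary_erosion(ribbon, structure=np.ones((3, 3)), border_value=0)
    boundary = ribbon & ~eroded
    rows, cols = np.nonzero(ribbon | piece)
    r0, r1 = max(int(rows.min()) - 5, 0), min(int(rows.max()) + 6, ribbon.shape[0])
    c0, c1 = max(int(cols.min()) - 5, 0), min(int(cols.max()) + 6, ribbon.shape[1])
    dist = ndimage.distance_transform_edt(~piece[r0:r1, c0:c1])
    local_boundary = boundary[r0:r1, c0:c1]
    n = int(local_boundary.sum())
    if n == 0:
        return 0.0
    return float(np.count_nonzero(dist[local_boundary] <= epsilon)) / n


def _build_event_tumor(
    scene: _Scene,
    rng: np.random.Generator,
    spec: TileSpec,
    event: PNIEvent,
    pts: np.ndarray,
    radius: float,
    ribbon: np.ndarray,
    ribbon_edt: np.ndarray,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Tumor mass realizing the event's target geometry against ``ribbon``.

    Returns (piece, body): the full painted tumor and the gland-cluster body
    guaranteed to lie in the event's main tumor component.

    Encirclement events get a tumor collar hugging a sub-path spanning the
    target fraction of the nerve, fused with a gland-cluster body; distance
    events get a cluster pushed along the local path normal until the
    measured gap matches the target.  Clearances against previously painted
    structures are enforced via the scene's cached distance maps (which do
    not yet include this event's ribbon).
    """
    h, w = scene.shape
    n_pts = len(pts)
    gland_r = rng.uniform(*spec.gland_radius_range)
    base_r = 0.8 * gland_r

    if event.target_encirclement > 0:
        # the attached tumor body and the collar's end caps add ~5-7% boundary
        # coverage beyond the sub-path span, so aim slightly below the target
        frac = 0.93 * event.target_encirclement
        span = max(3, int(round(frac * n_pts)))
        lo = int(rng.uniform(0, max(1, n_pts - span)))
        sub = pts[lo : lo + span]
        collar = _stamp_path(sub, radius + _BAND_WIDTH, scene.shape) & ~ribbon
        mid_i = lo + span // 2
        normal = _normal_at(pts, mid_i)
        center = pts[mid_i] + normal * (radius + _BAND_WIDTH + 0.8 * base_r)
        if not (1.3 * base_r <= center[0] <= h - 1.3 * base_r) or not (
            1.3 * base_r <= center[1] <= w - 1.3 * base_r
        ):
            center = pts[mid_i] - normal * (radius + _BAND_WIDTH + 0.8 * base_r)
        cluster = _gland_cluster(rng, center, gland_r, scene.shape)
        if not (collar & cluster).any():
            return None  # body detached from collar; would split the component
        if cluster.sum() < 0.9 * np.pi * base_r**2:
            return None  # clipped by the border; too small to be a tumor body
        if (cluster & ribbon).sum() > 0.15 * cluster.sum():
            return None  # nerve would carve the body into fragments
        piece = (collar | cluster) & ~ribbon
        body = cluster & ~ribbon
    else:
        # gland cluster pushed along the local normal to the target distance
        target = max(event.target_distance, 1.0)  # adjacency rasterizes to >= 1
        i = int(rng.uniform(0.25, 0.75) * n_pts)
        normal = _normal_at(pts, i) * (1 if rng.random() < 0.5 else -1)
        center = pts[i] + normal * (radius + target + base_r)
        lobes = _sample_lobes(rng, gland_r)
        piece = None
        for _ in range(8):
            cluster = _raster_cluster(center, base_r, lobes, scene.shape) & ~ribbon
            if not cluster.any():
                return None
            measured = float(ribbon_edt[cluster].min())
            err = measured - target
            if abs(err) <= 1.0:
                piece = cluster
                break
            center = center + normal * -err
        if piece is None:
            return None
        if piece.sum() < 0.9 * np.pi * base_r**2:
            return None  # clipped by the border; too small to be a tumor body
        body = piece

    if scene.gap_to_nerve(piece) < _TUMOR_NERVE_GAP:
        return None
    if scene.gap_to_tumor(piece) < _TUMOR_TUMOR_GAP:
        return None
    return piece, body


def _pair_min_distance(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Exact minimum pixel-center distance between two pixel sets."""
    if not mask_a.any() or not mask_b.any():
        return np.inf
    if (mask_a & mask_b).any():
        return 0.0
    dist = ndimage.distance_transform_edt(~mask_a)
    return float(dist[mask_b].min())


def generate_tile(
    spec: TileSpec,
    events: Sequence[PNIEvent] = (),
    render: bool = True,
    max_attempts: int = 100,
) -> tuple[np.ndarray | None, GroundTruth]:
    """Generate one tile: RGB rendering (optional) plus verified ground truth.

    Planted events are verified on the rasterized mask: the measured
    nerve-tumor minimum distance must lie within 2 px of the target and the
    measured encirclement within 0.1 of the target, else the attempt is
    redrawn (bounded).  Event structures are painted in addition to the
    spec's structure counts.  Identical spec and seed give bit-identical
    output.
    """
    rng = np.random.default_rng(spec.rng_seed)
    last_failure = "no attempts made"
    for _ in range(max_attempts):
        scene = _Scene((spec.height, spec.width))
        seeds: list[tuple[tuple[int, int], tuple[int, int]]] = []
        ok = True
        for i, event in enumerate(events):
            placed = _place_event(scene, rng, spec, event)
            if placed is None:
                ok, last_failure = False, f"event {i} placement failed"
                break
            seeds.append(placed)
        if not ok:
            continue
        for i in range(spec.n_nerves):
            if _place_nerve(scene, rng, spec) is None:
                ok, last_failure = False, f"nerve {i} placement failed"
                break
        if not ok:
            continue
        for i in range(spec.n_malignant_glands):
            if not _place_cluster(scene, rng, spec):
                ok, last_failure = False, f"malignant gland {i} placement failed"
                break
        if not ok:
            continue
        for i in range(spec.n_benign_glands):
            if not _place_benign(scene, rng, spec):
                ok, last_failure = False, f"benign gland {i} placement failed"
                break
        if not ok:
            continue

        mask = scene.class_mask()
        resolved = _verify_events(mask, events, seeds)
        if resolved is None:
            last_failure = "event verification (distance/encirclement) failed"
            continue
        gt = GroundTruth(class_mask=mask, events=resolved)
        rgb = render_tile(mask, rng, spec.background_noise_sd) if render else None
        return rgb, gt
    raise PlacementError(
        f"tile generation failed after {max_attempts} attempts "
        f"(seed {spec.rng_seed}): {last_failure}"
    )


def _verify_events(
    mask: np.ndarray,
    events: Sequence[PNIEvent],
    seeds: Sequence[tuple[tuple[int, int], tuple[int, int]]],
) -> list[PNIEvent] | None:
    if not events:
        return []
    nerve_regions = label_components(mask == NERVE, connectivity=8)
    tumor_regions = label_components(mask == TUMOR, connectivity=8)
    resolved = []
    for event, (nerve_seed, tumor_seed) in zip(events, seeds):
        nid = int(nerve_regions.labels[nerve_seed])
        tid = int(tumor_regions.labels[tumor_seed])
        if nid == 0 or tid == 0:
            return None
        d = _pair_min_distance(nerve_regions.labels == nid, tumor_regions.labels == tid)
        if abs(d - event.target_distance) > _EVENT_DISTANCE_TOL:
            return None
        enc = measure_encirclement(nid, nerve_regions, mask == TUMOR, epsilon=3.0)
        if abs(enc - event.target_encirclement) > _EVENT_ENCIRCLEMENT_TOL:
            return None
        resolved.append(dataclasses.replace(event, nerve_id=nid, tumor_id=tid))
    return resolved


# ---------------------------------------------------------------------------
# rendering


def render_tile(
    class_mask: np.ndarray, rng: np.random.Generator, noise_sd: float = 6.0
) -> np.ndarray:
    """Render an H&E-like RGB tile from a class mask.

    Appearance is procedural: an eosin-pink stroma with multi-octave noise,
    pink wavy fiber texture inside nerves, nucleus-speckled basophilic tumor,
    and pale benign glands with a darker epithelial rim.  Pixels are colored
    purely by their mask code, so rendering and annotation cannot disagree.
    """
    mask = np.asarray(class_mask)
    h, w = mask.shape
    img = np.empty((h, w, 3), dtype=np.float32)
    img[...] = (234.0, 205.0, 217.0)  # eosin stroma

    # multi-octave background texture
    texture = np.zeros((h, w), dtype=np.float32)
    for sigma, amp in ((2, 4.0), (8, 6.0), (24, 5.0)):
        texture += amp * ndimage.gaussian_filter(
            rng.standard_normal((h, w)).astype(np.float32), sigma
        ) * (sigma / 2.0)
    img += texture[..., None] * np.array([1.0, 0.9, 0.95], dtype=np.float32)

    rows = np.arange(h)[:, None] + 0 * np.arange(w)[None, :]
    wave = np.sin(rows / 6.0 + 3.0 * ndimage.gaussian_filter(
        rng.standard_normal((h, w)).astype(np.float32), 12
    ))

    nerve = mask == NERVE
    img[nerve] = np.array([228.0, 182.0, 198.0]) + (8.0 * wave[nerve])[:, None]

    tumor = mask == TUMOR
    nuclei = ndimage.gaussian_filter(rng.standard_normal((h, w)).astype(np.float32), 1.5)
    speckle = nuclei > np.quantile(nuclei, 0.75)
    img[tumor] = (188.0, 158.0, 202.0)
    img[tumor & speckle] = (112.0, 82.0, 146.0)

    benign = mask == BENIGN_GLAND
    img[benign] = (214.0, 192.0, 214.0)
    interior = ndimage.distance_transform_edt(benign)
    rim = benign & (interior <= 4)
    img[rim] = (140.0, 110.0, 160.0)

    img += rng.normal(0.0, noise_sd, size=(h, w, 1)).astype(np.float32)
    return np.clip(img, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# cases and studies


def draw_n_slides(spec: CaseSpec, rng: np.random.Generator) -> int:
    """Slide count from the case's truncated-normal distribution (>= 1)."""
    if spec.n_slides is not None:
        return spec.n_slides
    mean, sd = (
        (spec.tumor_only_mean, spec.tumor_only_sd)
        if spec.tumor_only
        else (spec.slides_mean, spec.slides_sd)
    )
    a = (0.5 - mean) / sd
    x = truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng)
    return max(1, int(np.floor(x + 0.5)))


def generate_case(
    spec: CaseSpec,
    seed: int,
    tile_spec: TileSpec | None = None,
    event_template: PNIEvent | None = None,
    render: bool = True,
) -> SyntheticCase:
    """Generate all slides of one case.

    For PNI-positive cases the ``n_events`` events are planted on distinct
    uniformly chosen slides (PNI is a rare event: most slides of a positive
    case contain none).
    """
    rng = np.random.default_rng(seed)
    base = tile_spec or TileSpec()
    template = event_template or PNIEvent()
    n_slides = draw_n_slides(spec, rng)

    events_per_slide = np.zeros(n_slides, dtype=int)
    if spec.n_events:
        chosen = rng.choice(n_slides, size=min(spec.n_events, n_slides), replace=False)
        events_per_slide[chosen] = 1
        for _ in range(spec.n_events - len(chosen)):
            events_per_slide[rng.integers(n_slides)] += 1

    slides = []
    for i in range(n_slides):
        slide_events = [dataclasses.replace(template) for _ in range(events_per_slide[i])]
        # an unlucky tile seed may exhaust its placement attempts; a few
        # reseeds keep whole-study generation robust while staying seeded
        for attempt in range(4):
            tspec = dataclasses.replace(base, rng_seed=int(rng.integers(2**31)))
            try:
                slides.append(generate_tile(tspec, slide_events, render=render))
                break
            except PlacementError:
                if attempt == 3:
                    raise
    return SyntheticCase(spec=dataclasses.replace(spec, n_slides=n_slides), slides=slides)


def study_case_specs(
    n_cases: int,
    prevalence: float,
    seed: int,
    n_tumor_only: int = 0,
    events_per_positive: int = 1,
    n_slides: int | None = None,
) -> list[tuple[CaseSpec, int]]:
    """Deterministic (CaseSpec, case seed) assignment for a study."""
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_pos = int(round(n_cases * prevalence))
    positive = np.zeros(n_cases, dtype=bool)
    positive[:n_pos] = True
    positive = positive[rng.permutation(n_cases)]
    tumor_only = np.zeros(n_cases, dtype=bool)
    if n_tumor_only:
        tumor_only[rng.choice(n_cases, size=min(n_tumor_only, n_cases), replace=False)] = True
    seeds = rng.integers(2**31, size=n_cases)
    out = []
    for i in range(n_cases):
        spec = CaseSpec(
            case_id=f"case_{i:03d}",
            pni_positive=bool(positive[i]),
            tumor_only=bool(tumor_only[i]),
            n_events=events_per_positive if positive[i] else 0,
            n_slides=n_slides,
        )
        out.append((spec, int(seeds[i])))
    return out


def generate_study(
    n_cases: int = 59,
    prevalence: float = 31 / 59,
    seed: int = 0,
    n_tumor_only: int = 0,
    events_per_positive: int = 1,
    tile_spec: TileSpec | None = None,
    render: bool = True,
    n_slides: int | None = None,
) -> tuple[list[SyntheticCase], dict]:
    """Generate a full study plus its manifest.

    Exactly round(n_cases * prevalence) cases are PNI-positive.  The manifest
    records per-case truth labels and generation seeds; the io module writes
    it (and the tiles) to disk.
    """
    cases = []
    manifest_cases = []
    for spec, case_seed in study_case_specs(
        n_cases, prevalence, seed, n_tumor_only, events_per_positive, n_slides=n_slides
    ):
        case = generate_case(spec, case_seed, tile_spec=tile_spec, render=render)
        cases.append(case)
        manifest_cases.append(
            {
                "case_id": spec.case_id,
                "pni_positive": spec.pni_positive,
                "tumor_only": spec.tumor_only,
                "n_slides": case.spec.n_slides,
                "n_events": case.n_events,
                "seed": case_seed,
            }
        )
    manifest = {"n_cases": n_cases, "prevalence": prevalence, "seed": seed, "cases": manifest_cases}
    return cases, manifest
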