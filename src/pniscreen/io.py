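"""Readers and writers for on-disk pipeline artifacts.

Conventions: RGB tiles are PNG or uncompressed TIFF (lossless round trips);
class masks are single-channel 8-bit PNG with codes 0-3; probability maps
are 2-channel 32-bit float TIFF; study manifests are YAML; candidates export
to CSV and GeoJSON (x = column, y = row, origin top-left, stated in the
file's properties); study summaries are JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from ._codes import MASK_CODES
from .clinical import StudySummary
from .proximity import Candidate
from .segmentation import ProbabilityMap

__all__ = [
    "read_tile",
    "write_tile",
    "read_mask",
    "write_mask",
    "read_probability_map",
    "write_probability_map",
    "read_manifest",
    "write_manifest",
    "candidates_to_csv",
    "candidates_to_geojson",
    "write_summary",
]

_PNG = {".png"}
_TIFF = {".tif", ".tiff"}


def _check_ext(path: Path, allowed: set[str]) -> str:
    ext = path.suffix.lower()
    if ext not in allowed:
        raise ValueError(f"unsupported extension {ext!r} for {path.name} (expected {sorted(allowed)})")
    return ext


def read_tile(path) -> np.ndarray:
    """Read an RGB tile from PNG or TIFF."""
    path = Path(path)
    ext = _check_ext(path, _PNG | _TIFF)
    try:
        arr = tifffile.imread(path) if ext in _TIFF else iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - normalize decoder errors
        raise IOError(f"could not parse image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError(f"{path} is not an RGB raster (shape {arr.shape})")
    return arr


def write_tile(path, tile: np.ndarray) -> None:
    path = Path(path)
    ext = _check_ext(path, _PNG | _TIFF)
    tile = np.asarray(tile, dtype=np.uint8)
    if ext in _TIFF:
        tifffile.imwrite(path, tile, compression=None)
    else:
        iio.imwrite(path, tile)


def read_mask(path) -> np.ndarray:
    """Read a single-channel class mask (codes 0-3) from PNG."""
    path = Path(path)
    _check_ext(path, _PNG)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"could not parse mask {path}: {exc}") from exc
    if arr.ndim != 2:
        raise ValueError(f"{path} is not single-channel (shape {arr.shape})")
    if not np.isin(arr, MASK_CODES).all():
        bad = sorted(set(np.unique(arr)) - set(MASK_CODES))
        raise ValueError(f"{path} contains invalid class codes {bad}")
    return arr.astype(np.uint8)


def write_mask(path, mask: np.ndarray) -> None:
    path = Path(path)
    _check_ext(path, _PNG)
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("class mask must be single-channel")
    if not np.isin(mask, MASK_CODES).all():
        raise ValueError("class mask contains codes outside 0..3")
    iio.imwrite(path, mask.astype(np.uint8))


def write_probability_map(path, pmap: ProbabilityMap) -> None:
    path = Path(path)
    _check_ext(path, _TIFF)
    tifffile.imwrite(
        path,
        pmap.values.astype(np.float32),
        compression=None,
        metadata={"provenance": pmap.provenance, "channels": "tumor,nerve"},
    )


def read_probability_map(path) -> ProbabilityMap:
    path = Path(path)
    _check_ext(path, _TIFF)
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"could not parse probability map {path}: {exc}") from exc
    return ProbabilityMap(values=np.asarray(arr, dtype=np.float32), provenance=str(path))


def write_manifest(path, manifest: dict) -> None:
    Path(path).write_text(yaml.safe_dump(manifest, sort_keys=False))


def read_manifest(path) -> dict:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict) or "cases" not in data:
        raise ValueError(f"{path} is not a study manifest")
    return data


def _candidate_row(c: Candidate, rank: int | None = None) -> dict:
    row = dataclasses.asdict(c)
    (nr, nc), (tr, tc) = c.closest_pair
    row["closest_pair"] = f"({nr},{nc})-({tr},{tc})"
    row["field_window"] = ",".join(str(v) for v in c.field_window)
    if rank is not None:
        row = {"rank": rank, **row}
    return row


def candidates_to_csv(path, candidates: Sequence[Candidate]) -> None:
    cols = [
        "rank", "slide_id", "nerve_id", "tumor_id", "min_distance", "encirclement",
        "closest_pair", "field_window", "nerve_area", "tumor_area",
    ]
    rows = [_candidate_row(c, rank=i + 1) for i, c in enumerate(candidates)]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def candidates_to_geojson(path, candidates: Sequence[Candidate]) -> None:
    """Candidate field windows as GeoJSON polygons in image coordinates."""
    features = []
    for i, c in enumerate(candidates):
        r0, c0, h, w = c.field_window
        ring = [[c0, r0], [c0 + w, r0], [c0 + w, r0 + h], [c0, r0 + h], [c0, r0]]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "rank": i + 1,
                    "slide_id": c.slide_id,
                    "nerve_id": c.nerve_id,
                    "tumor_id": c.tumor_id,
                    "min_distance": c.min_distance,
                    "encirclement": c.encirclement,
                },
            }
        )
    doc = {
        "type": "FeatureCollection",
        "properties": {
            "coordinate_system": "image pixels, x=column, y=row, origin top-left"
        },
        "features": features,
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def write_summary(path, summary: StudySummary) -> None:
    Path(path).write_text(json.dumps(summary.to_dict(), indent=2))
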