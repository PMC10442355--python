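"""Nerve/tumor segmenters producing per-class probability maps.

Two segmenters share one output contract (an H x W x 2 confidence raster with
channels (tumor, nerve), each an independent detector in [0, 1]):

* a trainable pixel classifier — per-pixel multiscale intensity/edge/texture
  features (scikit-image) fed to a small multilayer perceptron with two
  independent sigmoid output heads.  Benign glands are trained as background:
  only explicit tumor and nerve annotations are positive targets.
* an oracle-noise segmenter — corrupts a ground-truth mask with controlled
  error modes (dropped components, spurious small foci, boundary jitter,
  sub-unit confidences) so the downstream pipeline can be exercised, and its
  failure behavior studied, without any training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import joblib
import numpy as np
from scipy import ndimage
from skimage import color
from skimage.feature import multiscale_basic_features
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier

from ._codes import CLASS_CHANNELS, CLASS_CODES

if TYPE_CHECKING:  # pragma: no cover
    from .synthgen import GroundTruth

__all__ = [
    "ProbabilityMap",
    "SegmenterConfig",
    "NoiseModel",
    "PixelSegmenter",
    "augment",
    "train_pixel_segmenter",
    "predict",
    "oracle_noise_segment",
]


@dataclass
class ProbabilityMap:
    """Per-class confidence raster, channel order (tumor, nerve)."""

    values: np.ndarray  # float32, H x W x 2
    provenance: str = "unknown"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3 or self.values.shape[-1] != len(CLASS_CHANNELS):
            raise ValueError("ProbabilityMap.values must be H x W x 2")
        if self.values.min() < 0.0 or self.values.max() > 1.0:
            raise ValueError("confidences must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[:2]

    def channel(self, class_name: str) -> np.ndarray:
        return self.values[..., CLASS_CHANNELS[class_name]]


@dataclass(frozen=True)
class SegmenterConfig:
    """Hyperparameters of the trainable pixel classifier.

    ``depth`` sets the coarsest feature scale (sigma_max = 2**depth), playing
    the role an encoder depth plays in an encoder/decoder net;
    ``base_channels`` is the hidden-layer width of the MLP head.
    """

    depth: int = 3
    base_channels: int = 16
    epochs: int = 50
    learning_rate: float = 1e-3
    batch_size: int = 256
    augment: bool = True
    pixels_per_tile: int = 2000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """Controlled corruption of ground truth into a probability map.

    miss_rate is the fraction of true components dropped per tile per class
    (round(miss_rate * n) components, chosen uniformly); spurious_rate is the
    expected number of false components added per tile per class (Poisson),
    each with pixel area uniform in spurious_area_range and placed disjoint
    from true nerve/tumor tissue (they may overlap benign glands, mimicking
    benign glands misread as tumor).  Confidences are drawn per component from
    clipped normals (mean, sd).
    """

    miss_rate: float = 0.0
    spurious_rate: float = 0.0
    spurious_area_range: tuple[float, float] = (500.0, 5000.0)
    boundary_jitter: int = 0
    confidence_in: tuple[float, float] = (1.0, 0.0)
    confidence_out: tuple[float, float] = (0.85, 0.05)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.miss_rate <= 1.0:
            raise ValueError("miss_rate must lie in [0, 1]")
        if self.spurious_rate < 0:
            raise ValueError("spurious_rate must be >= 0")
        lo, hi = self.spurious_area_range
        if not 0 < lo <= hi:
            raise ValueError("spurious_area_range must satisfy 0 < lo <= hi")
        if self.boundary_jitter < 0:
            raise ValueError("boundary_jitter must be >= 0")


# ---------------------------------------------------------------------------
# augmentation

_GEOMETRIC_OPS = ("identity", "hflip", "vflip", "rot90", "rot180", "rot270")
_PHOTOMETRIC_OPS = ("brightness", "hue")
AUGMENT_OPS = _GEOMETRIC_OPS + _PHOTOMETRIC_OPS


def _apply_geometric(arr: np.ndarray, op: str) -> np.ndarray:
    if op == "identity":
        return arr.copy()
    if op == "hflip":
        return arr[:, ::-1].copy()
    if op == "vflip":
        return arr[::-1, :].copy()
    if op.startswith("rot"):
        k = {"rot90": 1, "rot180": 2, "rot270": 3}[op]
        return np.rot90(arr, k=k, axes=(0, 1)).copy()
    raise ValueError(f"unknown geometric op {op!r}")


def augment(
    tile: np.ndarray, mask: np.ndarray, seed: int, op: str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one randomly drawn augmentation to a tile and its mask.

    Geometric transforms (flips, right-angle rotations) are applied
    identically to tile and mask; photometric jitter (brightness, hue) touches
    the tile only.  Class codes are never altered.
    """
    tile = np.asarray(tile)
    mask = np.asarray(mask)
    if tile.shape[:2] != mask.shape[:2]:
        raise ValueError("tile and mask shapes differ")
    rng = np.random.default_rng(seed)
    if op is None:
        op = AUGMENT_OPS[rng.integers(len(AUGMENT_OPS))]
    if op in _GEOMETRIC_OPS:
        return _apply_geometric(tile, op), _apply_geometric(mask, op)
    if op == "brightness":
        scale = rng.uniform(0.85, 1.15)
        out = np.clip(tile.astype(np.float32) * scale, 0, 255).astype(tile.dtype)
        return out, mask.copy()
    if op == "hue":
        hsv = color.rgb2hsv(tile)
        hsv[..., 0] = (hsv[..., 0] + rng.uniform(-0.03, 0.03)) % 1.0
        out = np.clip(color.hsv2rgb(hsv) * 255, 0, 255).astype(tile.dtype)
        return out, mask.copy()
    raise ValueError(f"unknown augmentation op {op!r}")


# ---------------------------------------------------------------------------
# trainable pixel classifier


@dataclass
class PixelSegmenter:
    """Serializable trained segmenter: feature recipe + MLP head."""

    config: SegmenterConfig
    classifier: MLPClassifier
    loss_curve: list[float]

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "PixelSegmenter":
        model = joblib.load(path)
        if not isinstance(model, PixelSegmenter):
            raise TypeError(f"{path} does not contain a PixelSegmenter")
        return model


def _features(tile: np.ndarray, depth: int) -> np.ndarray:
    img = np.asarray(tile, dtype=np.float32) / 255.0
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("expected an RGB tile (H x W x 3)")
    return multiscale_basic_features(
        img,
        channel_axis=-1,
        intensity=True,
        edges=True,
        texture=True,
        sigma_min=1.0,
        sigma_max=float(2**depth),
    )


def _targets(mask: np.ndarray) -> np.ndarray:
    """Two binary columns (tumor, nerve); benign glands count as background."""
    y = np.zeros(mask.shape + (2,), dtype=np.int8)
    for cls, ch in CLASS_CHANNELS.items():
        y[..., ch] = mask == CLASS_CODES[cls]
    return y


def train_pixel_segmenter(
    tiles: Sequence[np.ndarray],
    masks: Sequence[np.ndarray],
    config: SegmenterConfig = SegmenterConfig(),
) -> PixelSegmenter:
    """Fit the pixel classifier on annotated tiles.

    Pixels are subsampled per tile with foreground classes oversampled so the
    rare nerve/tumor pixels are not swamped by background.  Raises if fewer
    than 8 tiles are supplied or the final loss is non-finite.
    """
    if len(tiles) != len(masks):
        raise ValueError("tiles and masks must align 1:1")
    if len(tiles) < 8:
        raise ValueError(f"need at least 8 training tiles, got {len(tiles)}")
    rng = np.random.default_rng(config.rng_seed)

    xs, ys = [], []
    for i, (tile, mask) in enumerate(zip(tiles, masks)):
        pairs = [(tile, mask)]
        if config.augment:
            pairs.append(augment(tile, mask, seed=int(rng.integers(2**31))))
        for t, m in pairs:
            feats = _features(t, config.depth)
            targ = _targets(np.asarray(m))
            flat_x = feats.reshape(-1, feats.shape[-1])
            flat_y = targ.reshape(-1, 2)
            fg = flat_y.any(axis=1)
            n_fg = min(int(fg.sum()), config.pixels_per_tile // 2)
            n_bg = config.pixels_per_tile - n_fg
            idx_fg = rng.choice(np.flatnonzero(fg), size=n_fg, replace=False) if n_fg else []
            bg_pool = np.flatnonzero(~fg)
            idx_bg = rng.choice(bg_pool, size=min(n_bg, bg_pool.size), replace=False)
            idx = np.concatenate([np.asarray(idx_fg, dtype=np.int64), idx_bg])
            xs.append(flat_x[idx])
            ys.append(flat_y[idx])

    X = np.concatenate(xs)
    Y = np.concatenate(ys)
    clf = MLPClassifier(
        hidden_layer_sizes=(config.base_channels,),
        max_iter=config.epochs,
        learning_rate_init=config.learning_rate,
        batch_size=min(config.batch_size, len(X)),
        random_state=config.rng_seed,
        solver="adam",
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, Y)
    loss_curve = [float(v) for v in clf.loss_curve_]
    if not np.isfinite(loss_curve[-1]):
        raise ArithmeticError(
            f"training diverged: final loss {loss_curve[-1]} after "
            f"{len(loss_curve)} epochs (lr={config.learning_rate})"
        )
    return PixelSegmenter(config=config, classifier=clf, loss_curve=loss_curve)


def predict(model: PixelSegmenter, tile: np.ndarray) -> ProbabilityMap:
    """Predict per-pixel (tumor, nerve) confidences for one RGB tile."""
    feats = _features(tile, model.config.depth)
    h, w, f = feats.shape
    proba = model.classifier.predict_proba(feats.reshape(-1, f))
    proba = np.asarray(proba, dtype=np.float32).reshape(h, w, 2)
    return ProbabilityMap(
        values=np.clip(proba, 0.0, 1.0),
        provenance=f"pixel_classifier(seed={model.config.rng_seed})",
    )


# ---------------------------------------------------------------------------
# oracle-noise segmenter

_STRUCT8 = np.ones((3, 3), dtype=bool)


def _clipped_normal(rng: np.random.Generator, mean_sd: tuple[float, float]) -> float:
    mean, sd = mean_sd
    if sd == 0:
        return float(np.clip(mean, 0.0, 1.0))
    return float(np.clip(rng.normal(mean, sd), 0.0, 1.0))


def _jitter_component(comp: np.ndarray, radius: int) -> np.ndarray:
    if radius == 0:
        return comp
    if radius > 0:
        dist = ndimage.distance_transform_edt(~comp)
        return dist <= radius
    dist = ndimage.distance_transform_edt(comp)
    return dist > -radius


def _spurious_blob(
    rng: np.random.Generator, shape: tuple[int, int], area: float, forbidden: np.ndarray
) -> np.ndarray | None:
    """A roughly round blob of ~area pixels, disjoint from forbidden tissue."""
    h, w = shape
    radius = max(2.0, np.sqrt(area / np.pi))
    for _ in range(50):
        r = rng.uniform(radius, h - radius) if h > 2 * radius else h / 2
        c = rng.uniform(radius, w - radius) if w > 2 * radius else w / 2
        rr, cc = np.ogrid[:h, :w]
        # mild elliptical anisotropy so spurious foci are not perfect disks
        ar = rng.uniform(0.75, 1.3)
        blob = ((rr - r) / radius) ** 2 + ((cc - c) / (radius * ar)) ** 2 <= 1.0
        if not (blob & forbidden).any():
            return blob
    return None


def oracle_noise_segment(
    gt: "GroundTruth | np.ndarray", noise: NoiseModel = NoiseModel()
) -> ProbabilityMap:
    """Corrupt a ground-truth class mask into a probability map.

    With a zero NoiseModel the output is exactly 1.0 on each class's pixels
    and 0.0 elsewhere, so binarizing at any threshold in (0, 1] reproduces the
    ground truth.
    """
    mask = np.asarray(getattr(gt, "class_mask", gt))
    rng = np.random.default_rng(noise.rng_seed)
    h, w = mask.shape
    values = np.zeros((h, w, 2), dtype=np.float32)
    # spurious foci must avoid true nerve/tumor tissue (benign glands allowed)
    true_tissue = np.isin(mask, [CLASS_CODES["tumor"], CLASS_CODES["nerve"]])
    forbidden = ndimage.binary_dilation(true_tissue, structure=_STRUCT8, iterations=2)

    for cls, ch in CLASS_CHANNELS.items():
        class_mask = mask == CLASS_CODES[cls]
        labels, n = ndimage.label(class_mask, structure=_STRUCT8)
        n_drop = int(np.floor(noise.miss_rate * n + 0.5))
        dropped = set(rng.choice(np.arange(1, n + 1), size=n_drop, replace=False)) if n_drop else set()
        for k in range(1, n + 1):
            if k in dropped:
                continue
            comp = labels == k
            if noise.boundary_jitter:
                j = int(rng.integers(-noise.boundary_jitter, noise.boundary_jitter + 1))
                jittered = _jitter_component(comp, j)
                # dilation must not bleed into neighboring true tissue
                jittered &= ~(true_tissue & ~comp)
                comp = jittered
            conf = _clipped_normal(rng, noise.confidence_in)
            values[..., ch][comp] = conf
        n_spurious = rng.poisson(noise.spurious_rate)
        for _ in range(n_spurious):
            area = rng.uniform(*noise.spurious_area_range)
            blob = _spurious_blob(rng, (h, w), area, forbidden)
            if blob is None:
                continue
            conf = _clipped_normal(rng, noise.confidence_out)
            np.maximum(values[..., ch], np.where(blob, conf, 0.0), out=values[..., ch])

    return ProbabilityMap(
        values=values,
        provenance=f"oracle_noise(seed={noise.rng_seed})",
    )
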