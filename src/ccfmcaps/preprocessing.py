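"""Contrast-limited adaptive histogram equalization (CLAHE) and data loading.

CLAHE here is the parameter-free contrast layer that feeds the first lane of
the two-lane capsule network.  The image is divided into a grid of tiles and
each tile is histogram-equalized *independently*: the tile histogram is
clipped at ``clip_limit`` times the mean bin count, the clipped excess is
redistributed uniformly, and the resulting CDF becomes the intensity
mapping.  There is no inter-tile interpolation — every tile is enhanced on
its own, which bounds noise amplification per tile and keeps the operation
strictly local.

Colour images are handled in CIE L*a*b* by default: only the lightness
channel is equalized and the chroma channels pass through, which avoids hue
shifts.  The operation introduces no learnable parameters.

The module also provides the contrast-gain diagnostic (ratio of processed to
original contrast, logged but never trained on) and the stratified
directory-per-class dataset loader with the 80:20 split used throughout.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import yaml
from skimage.color import lab2rgb, rgb2gray, rgb2lab
from skimage.transform import resize

__all__ = [
    "ClaheConfig",
    "SplitSpec",
    "validate_image",
    "apply_clahe",
    "contrast_gain",
    "load_dataset",
    "stratified_split",
    "load_config",
]

_N_BINS = 256  # histogram resolution of the equalization mapping


@dataclass
class ClaheConfig:
    """Tile grid, clip factor and colour handling for the contrast layer.

    clip_limit
        Histogram clip ceiling as a multiple of the mean bin count;
        must be positive.  Values near 1 barely equalize, large values
        approach plain per-tile histogram equalization.
    tile_grid
        (rows, cols) of independently equalized tiles.
    colour_mode
        ``"luminance"`` equalizes L* only (3-channel input required);
        ``"per_channel"`` equalizes each channel separately.
    """

    clip_limit: float = 2.0
    tile_grid: tuple[int, int] = (8, 8)
    colour_mode: str = "luminance"

    def __post_init__(self) -> None:
        if self.clip_limit <= 0:
            raise ValueError("clip_limit must be > 0")
        r, c = self.tile_grid
        if r < 1 or c < 1:
            raise ValueError("tile_grid entries must be >= 1")
        if self.colour_mode not in ("luminance", "per_channel"):
            raise ValueError(f"unknown colour_mode {self.colour_mode!r}")


@dataclass
class SplitSpec:
    """Stratified train/test split specification (default 80:20)."""

    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")


def validate_image(image: np.ndarray) -> np.ndarray:
    """Check the [0,1], 1-or-3-channel image contract; return float64 view."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        img = img[..., None]
    if img.ndim != 3 or img.shape[2] not in (1, 3):
        raise ValueError(f"expected HxW, HxWx1 or HxWx3 image, got {image.shape}")
    if img.size == 0:
        raise ValueError("empty image")
    if img.min() < -1e-9 or img.max() > 1 + 1e-9:
        raise ValueError("pixel intensities must lie in [0, 1]")
    return np.clip(img, 0.0, 1.0)


def _equalize_tile(tile: np.ndarray, clip_limit: float) -> np.ndarray:
    """Clipped histogram equalization of one tile of [0,1] intensities."""
    q = np.minimum((tile * _N_BINS).astype(np.intp), _N_BINS - 1)
    hist = np.bincount(q.ravel(), minlength=_N_BINS).astype(np.float64)
    ceiling = clip_limit * tile.size / _N_BINS
    excess = np.maximum(hist - ceiling, 0.0).sum()
    hist = np.minimum(hist, ceiling) + excess / _N_BINS
    cdf = np.cumsum(hist)
    lut = cdf / cdf[-1]
    return lut[q]


def _clahe_single_channel(channel: np.ndarray, cfg: ClaheConfig) -> np.ndarray:
    h, w = channel.shape
    rows, cols = cfg.tile_grid
    if rows > h or cols > w:
        raise ValueError(
            f"tile_grid {cfg.tile_grid} larger than image {channel.shape}")
    out = np.empty_like(channel)
    row_edges = np.linspace(0, h, rows + 1).astype(int)
    col_edges = np.linspace(0, w, cols + 1).astype(int)
    for r in range(rows):
        for c in range(cols):
            sl = (slice(row_edges[r], row_edges[r + 1]),
                  slice(col_edges[c], col_edges[c + 1]))
            out[sl] = _equalize_tile(channel[sl], cfg.clip_limit)
    return out


def apply_clahe(image: np.ndarray, cfg: ClaheConfig | None = None) -> np.ndarray:
    """Tile-wise contrast-limited histogram equalization.

    Shape-preserving, values stay in [0, 1], zero learnable parameters.
    """
    cfg = cfg or ClaheConfig()
    img = validate_image(image)
    squeeze = np.asarray(image).ndim == 2
    if img.shape[2] == 1:
        out = _clahe_single_channel(img[..., 0], cfg)[..., None]
    elif cfg.colour_mode == "per_channel":
        out = np.stack([_clahe_single_channel(img[..., k], cfg)
                        for k in range(3)], axis=-1)
    else:  # luminance: equalize L* only, keep chroma
        lab = rgb2lab(img)
        lab[..., 0] = _clahe_single_channel(lab[..., 0] / 100.0, cfg) * 100.0
        out = np.clip(lab2rgb(lab), 0.0, 1.0)
    out = np.clip(out, 0.0, 1.0)
    return out[..., 0] if squeeze else out


def _mean_contrast(image: np.ndarray) -> float:
    """Scalar contrast of an image: standard deviation of its luminance."""
    img = validate_image(image)
    gray = img[..., 0] if img.shape[2] == 1 else rgb2gray(img)
    return float(gray.std())


def contrast_gain(original: np.ndarray, processed: np.ndarray) -> float:
    """Diagnostic ratio of processed to original contrast.

    Reported in logs only; never enters training.  Raises on a
    zero-contrast original, where the ratio is undefined.
    """
    if np.asarray(original).shape != np.asarray(processed).shape:
        raise ValueError("original and processed images must share a shape")
    denom = _mean_contrast(original)
    if denom == 0.0:
        raise ValueError("contrast gain undefined: original image has zero contrast")
    return _mean_contrast(processed) / denom


def stratified_split(labels: np.ndarray, spec: SplitSpec
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per-class deterministic split; train count = floor(fraction * n)."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(spec.seed)
    train_idx, test_idx = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = rng.permutation(idx)
        n_train = int(np.floor(spec.train_fraction * idx.size))
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


_IMG_EXT = (".png", ".jpg", ".jpeg")


def load_dataset(directory: str,
                 target_shape: tuple[int, int, int] = (32, 32, 3),
                 split: SplitSpec | None = None):
    """Load a directory-per-class image tree, resize, and split 80:20.

    Returns ``(X_train, y_train), (X_test, y_test), class_names`` with images
    as float arrays in [0, 1] of shape ``target_shape`` (bilinear resize).
    Class directories are read in sorted order; the per-class split is
    stratified and deterministic given ``split.seed``.
    """
    split = split or SplitSpec()
    h, w, c = target_shape
    class_names = sorted(
        d for d in os.listdir(directory)
        if os.path.isdir(os.path.join(directory, d)))
    if not class_names:
        raise ValueError(f"no class directories found under {directory!r}")
    images, labels = [], []
    for ci, cname in enumerate(class_names):
        cdir = os.path.join(directory, cname)
        files = sorted(f for f in os.listdir(cdir)
                       if f.lower().endswith(_IMG_EXT))
        if not files:
            raise ValueError(f"class directory {cname!r} contains no images")
        for fname in files:
            arr = np.asarray(iio.imread(os.path.join(cdir, fname)))
            if arr.dtype == np.uint8:
                arr = arr.astype(np.float64) / 255.0
            if arr.ndim == 2:
                arr = arr[..., None]
            if arr.shape[2] == 4:  # drop alpha
                arr = arr[..., :3]
            if c == 3 and arr.shape[2] == 1:
                arr = np.repeat(arr, 3, axis=2)
            elif c == 1 and arr.shape[2] == 3:
                arr = rgb2gray(arr)[..., None]
            if arr.shape[:2] != (h, w):
                arr = resize(arr, (h, w), order=1, anti_aliasing=True)
            images.append(np.clip(arr, 0.0, 1.0))
            labels.append(ci)
    X = np.stack(images)
    y = np.asarray(labels, dtype=np.intp)
    tr, te = stratified_split(y, split)
    return (X[tr], y[tr]), (X[te], y[te]), class_names


def load_config(path: str) -> dict:
    """Read a YAML or JSON config with the documented preprocessing keys."""
    with open(path) as fh:
        cfg = json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path!r} did not parse to a mapping")
    if "tile_grid" in cfg:
        cfg["tile_grid"] = tuple(cfg["tile_grid"])
    return cfg
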