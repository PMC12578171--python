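"""Deterministic generator of class-separable leaf-like images.

Real leaf-disease corpora (PlantVillage-style) are heavily imbalanced, the
images within a class are near-duplicates of one another, and the backgrounds
are not uniform.  This module emulates those properties at thumbnail scale so
that every stage of the pipeline — contrast enhancement, colour-difference
features, capsule training, evaluation — can be exercised without downloading
anything.

Each class is an *archetype*: a base leaf colour, a lesion budget, a lesion
shape (round spots or elongated streaks) and a background mode.  Images are
rendered as an anti-aliased leaf ellipse with lesions scattered inside it,
plus optional clutter and pixel noise.  Every image is drawn from its own
counter-based random stream keyed by ``(seed, class index, image index)`` so
reproducibility does not depend on generation order.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np

__all__ = [
    "ClassArchetype",
    "LeafImageSpec",
    "generate",
    "easy_preset",
    "imbalanced_preset",
    "toy_fixture",
    "write_dataset",
]


@dataclass
class ClassArchetype:
    """Rendering recipe for one synthetic class."""

    name: str
    n_samples: int
    leaf_rgb: tuple[float, float, float] = (0.18, 0.55, 0.20)
    lesion_rgb: tuple[float, float, float] = (0.45, 0.28, 0.10)
    n_lesions: tuple[int, int] = (0, 0)  # inclusive range
    lesion_shape: str = "spot"  # "spot" | "streak"
    background: str = "plain"  # "plain" | "cluttered"


@dataclass
class LeafImageSpec:
    """Full specification of a synthetic dataset."""

    classes: list[ClassArchetype]
    image_size: tuple[int, int] = (32, 32)
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ValueError("a dataset needs at least two classes")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for arch in self.classes:
            if arch.n_samples <= 0:
                raise ValueError(f"class {arch.name!r} requests zero samples")
            if arch.lesion_shape not in ("spot", "streak"):
                raise ValueError(f"unknown lesion shape {arch.lesion_shape!r}")
            if arch.background not in ("plain", "cluttered"):
                raise ValueError(f"unknown background {arch.background!r}")


def _ellipse_mask(h: int, w: int, cy: float, cx: float, ry: float, rx: float,
                  angle: float = 0.0) -> np.ndarray:
    """Soft-edged (anti-aliased) ellipse membership in [0, 1]."""
    yy, xx = np.mgrid[0:h, 0:w]
    y = yy - cy
    x = xx - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = (ca * x + sa * y) / max(rx, 1e-6)
    v = (-sa * x + ca * y) / max(ry, 1e-6)
    r = np.sqrt(u * u + v * v)
    # ~1 px wide soft edge relative to the minor radius
    edge = 1.0 / max(min(rx, ry), 1.0)
    return np.clip((1.0 - r) / edge + 0.5, 0.0, 1.0)


def _render_one(arch: ClassArchetype, size: tuple[int, int],
                noise_sigma: float, rng: np.random.Generator) -> np.ndarray:
    h, w = size
    img = np.empty((h, w, 3), dtype=np.float64)

    # background
    if arch.background == "plain":
        base = np.array([0.72, 0.66, 0.55]) + rng.normal(0, 0.02, 3)
        img[:] = np.clip(base, 0, 1)
    else:
        # low-frequency clutter: coarse random field blown up to full size
        coarse = rng.random((4, 4, 3)) * 0.5 + 0.3
        reps = (int(np.ceil(h / 4)), int(np.ceil(w / 4)))
        field = np.repeat(np.repeat(coarse, reps[0], axis=0), reps[1], axis=1)
        img[:] = field[:h, :w]

    # leaf body
    leaf = np.clip(np.asarray(arch.leaf_rgb) + rng.normal(0, 0.03, 3), 0, 1)
    ry = h * rng.uniform(0.32, 0.40)
    rx = w * rng.uniform(0.26, 0.36)
    cy = h / 2 + rng.uniform(-1.5, 1.5)
    cx = w / 2 + rng.uniform(-1.5, 1.5)
    tilt = rng.uniform(-0.5, 0.5)
    mask = _ellipse_mask(h, w, cy, cx, ry, rx, tilt)
    img = img * (1 - mask[..., None]) + leaf * mask[..., None]

    # lesions inside the leaf
    lo, hi = arch.n_lesions
    n_les = int(rng.integers(lo, hi + 1)) if hi >= lo and hi > 0 else 0
    lesion = np.clip(np.asarray(arch.lesion_rgb) + rng.normal(0, 0.03, 3), 0, 1)
    for _ in range(n_les):
        ly = cy + rng.uniform(-0.6, 0.6) * ry
        lx = cx + rng.uniform(-0.6, 0.6) * rx
        if arch.lesion_shape == "spot":
            lr = rng.uniform(1.2, 2.5)
            lm = _ellipse_mask(h, w, ly, lx, lr, lr)
        else:  # streak
            lm = _ellipse_mask(h, w, ly, lx, rng.uniform(0.8, 1.4),
                               rng.uniform(3.0, 6.0), rng.uniform(0, np.pi))
        lm = lm * mask  # clip lesions to the leaf
        img = img * (1 - lm[..., None]) + lesion * lm[..., None]

    if noise_sigma > 0:
        img = img + rng.normal(0, noise_sigma, img.shape)
    return np.clip(img, 0.0, 1.0)


def generate(spec: LeafImageSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render the dataset described by ``spec``.

    Returns
    -------
    images : (N, H, W, 3) float array in [0, 1]
    labels : (N,) int array, class index per image

    The output is bit-identical for identical specs: image ``i`` of class
    ``c`` is rendered from ``default_rng([seed, c, i])`` regardless of what
    else is generated.
    """
    h, w = spec.image_size
    images, labels = [], []
    for c, arch in enumerate(spec.classes):
        for i in range(arch.n_samples):
            rng = np.random.default_rng([spec.seed, c, i])
            images.append(_render_one(arch, (h, w), spec.noise_sigma, rng))
            labels.append(c)
    return np.stack(images), np.asarray(labels, dtype=np.intp)


def easy_preset(per_class: int = 100, image_size: tuple[int, int] = (32, 32),
                seed: int = 0) -> LeafImageSpec:
    """Plain-background, high-contrast two-class set: healthy vs spotted.

    This is the smoke-training benchmark configuration: classes are
    separable by lesion statistics alone, so a trained classifier should
    approach perfect training accuracy quickly.
    """
    return LeafImageSpec(
        classes=[
            ClassArchetype("healthy", per_class,
                           leaf_rgb=(0.15, 0.58, 0.18), n_lesions=(0, 0)),
            ClassArchetype("spotted", per_class,
                           leaf_rgb=(0.30, 0.50, 0.15),
                           lesion_rgb=(0.55, 0.30, 0.08),
                           n_lesions=(4, 7), lesion_shape="spot"),
        ],
        image_size=image_size,
        noise_sigma=0.02,
        seed=seed,
    )


def imbalanced_preset(scale: float = 0.1, image_size: tuple[int, int] = (32, 32),
                      seed: int = 0) -> LeafImageSpec:
    """Three-class set with a 152:1000:1000 class-count ratio, scaled.

    Mirrors the strong imbalance seen in real potato leaf-disease corpora
    (a small healthy class against two large disease classes), reduced by
    ``scale`` so it stays desk-sized.
    """
    counts = [max(1, round(n * scale)) for n in (152, 1000, 1000)]
    return LeafImageSpec(
        classes=[
            ClassArchetype("healthy", counts[0],
                           leaf_rgb=(0.15, 0.58, 0.18), n_lesions=(0, 0),
                           background="cluttered"),
            ClassArchetype("early_blight", counts[1],
                           leaf_rgb=(0.28, 0.48, 0.14),
                           lesion_rgb=(0.42, 0.26, 0.08),
                           n_lesions=(3, 6), lesion_shape="spot",
                           background="cluttered"),
            ClassArchetype("late_blight", counts[2],
                           leaf_rgb=(0.22, 0.45, 0.16),
                           lesion_rgb=(0.25, 0.18, 0.16),
                           n_lesions=(2, 4), lesion_shape="streak",
                           background="cluttered"),
        ],
        image_size=image_size,
        noise_sigma=0.03,
        seed=seed,
    )


#: The documented 4x4 two-colour toy image used by the colour-difference
#: oracles: left 2x4 block saturated red, right 2x4 block saturated green.
TWO_COLOUR_4X4 = np.zeros((4, 4, 3))
TWO_COLOUR_4X4[:, :2, 0] = 1.0
TWO_COLOUR_4X4[:, 2:, 1] = 1.0
TWO_COLOUR_4X4.setflags(write=False)

_RANDOM_NAME = re.compile(r"^random_(\d+)x(\d+)$")


def toy_fixture(name: str, seed: int = 0) -> np.ndarray:
    """Canonical deterministic fixtures for the feature-extraction oracles.

    ``constant``        8x8x3 mid-grey.
    ``checkerboard``    16x16 single-channel low-contrast checkerboard
                        (0.45 / 0.55), for tile-wise equalization checks.
    ``step_edge``       8x8 single-channel, left half 0, right half 1.
    ``two_colour_4x4``  the documented red/green 4x4x3 block image.
    ``random_NxM``      NxMx3 uniform noise drawn from ``default_rng(seed)``.
    """
    if name == "constant":
        return np.full((8, 8, 3), 0.5)
    if name == "checkerboard":
        yy, xx = np.mgrid[0:16, 0:16]
        return np.where((yy + xx) % 2 == 0, 0.45, 0.55).astype(np.float64)
    if name == "step_edge":
        img = np.zeros((8, 8))
        img[:, 4:] = 1.0
        return img
    if name == "two_colour_4x4":
        return TWO_COLOUR_4X4.copy()
    m = _RANDOM_NAME.match(name)
    if m:
        h, w = int(m.group(1)), int(m.group(2))
        return np.random.default_rng(seed).random((h, w, 3))
    raise KeyError(f"unknown toy fixture {name!r}")


def write_dataset(images: np.ndarray, labels: np.ndarray,
                  class_names: list[str], out_dir: str) -> None:
    """Write images as 8-bit PNGs in directory-per-class layout."""
    for c, cname in enumerate(class_names):
        cdir = os.path.join(out_dir, cname)
        os.makedirs(cdir, exist_ok=True)
        idx = np.flatnonzero(labels == c)
        for j, i in enumerate(idx):
            arr = np.clip(np.round(images[i] * 255), 0, 255).astype(np.uint8)
            iio.imwrite(os.path.join(cdir, f"{cname}_{j:04d}.png"), arr)
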