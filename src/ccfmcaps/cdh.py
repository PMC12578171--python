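"""Colour-difference histogram (CDH) features.

The CDH descriptor accumulates perceptually-uniform Lab colour differences
between neighbouring pixels, gated by agreement of quantized indices: for
every unordered pixel pair at Chebyshev distance ``D``,

* if the two pixels fall in the same *edge-orientation* bin, the Euclidean
  Lab difference sqrt(dL^2 + da^2 + db^2) is added to the colour histogram
  at the first pixel's colour index;
* if the two pixels share the same *colour* index, the same difference is
  added to the orientation histogram at the first pixel's orientation bin.

The two histograms (lengths ``W`` and ``V``) are concatenated into a single
``W + V`` descriptor — 90-dimensional at the standard W=72, V=18.

Beyond the global descriptor, this module exposes the image-shaped
*feature map* that feeds the second lane of the capsule network: channel 1
holds each pixel's orientation-gated colour-difference mass, channel 2 its
colour-gated mass, channel 3 the gradient magnitude; each channel is
max-normalized to [0, 1].  Summed over pixels before normalization,
channels 1 and 2 reproduce the histogram totals exactly, so the map is the
spatial disaggregation of the descriptor.  The layer has no learnable
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import sobel
from skimage.color import rgb2lab

from .preprocessing import validate_image

__all__ = [
    "CdhConfig",
    "rgb_to_lab",
    "quantize_colour",
    "edge_orientation",
    "cdh_descriptor",
    "cdh_feature_map",
]

# CIE ranges used for uniform colour binning
_L_RANGE = (0.0, 100.0)
_A_RANGE = (-128.0, 127.0)
_B_RANGE = (-128.0, 127.0)


@dataclass
class CdhConfig:
    """Quantization levels and neighbourhood distance.

    W : number of colour bins (product of the per-channel ``lab_bins``).
    V : number of edge-orientation bins over [0, 180) degrees.
    D : Chebyshev neighbour distance (1 = the 8-neighbourhood).
    lab_bins : (n_L, n_a, n_b) uniform bins per Lab channel.
    """

    W: int = 72
    V: int = 18
    D: int = 1
    lab_bins: tuple[int, int, int] = (8, 3, 3)

    def __post_init__(self) -> None:
        if self.W < 1 or self.V < 1 or self.D < 1:
            raise ValueError("W, V and D must all be >= 1")
        nl, na, nb = self.lab_bins
        if nl * na * nb != self.W:
            raise ValueError(
                f"lab_bins {self.lab_bins} do not factorize W={self.W}")


def rgb_to_lab(image: np.ndarray) -> np.ndarray:
    """sRGB (D65) to CIE L*a*b*; grayscale inputs are replicated to RGB."""
    img = validate_image(image)
    if img.shape[2] == 1:
        img = np.repeat(img, 3, axis=2)
    return rgb2lab(img)


def _bin_channel(values: np.ndarray, lo: float, hi: float, n: int) -> np.ndarray:
    # half-open uniform bins [lo, hi); the top edge falls in the last bin
    idx = np.floor((np.clip(values, lo, hi) - lo) / (hi - lo) * n).astype(np.intp)
    return np.minimum(idx, n - 1)


def quantize_colour(lab: np.ndarray, cfg: CdhConfig | None = None) -> np.ndarray:
    """Per-pixel colour index in [0, W): row-major over (L, a, b) bins."""
    cfg = cfg or CdhConfig()
    nl, na, nb = cfg.lab_bins
    bl = _bin_channel(lab[..., 0], *_L_RANGE, nl)
    ba = _bin_channel(lab[..., 1], *_A_RANGE, na)
    bb = _bin_channel(lab[..., 2], *_B_RANGE, nb)
    return bl * (na * nb) + ba * nb + bb


def edge_orientation(lab: np.ndarray, cfg: CdhConfig | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Orientation bins and gradient magnitudes of the lightness channel.

    The L* gradient is taken with 3x3 Sobel operators (reflect boundary).
    The gradient angle, measured from the x-axis and folded into
    [0, 180) degrees, is binned uniformly into ``V`` levels.

    Returns ``(bins, magnitude)``; zero-gradient pixels land in bin 0.
    """
    cfg = cfg or CdhConfig()
    L = lab[..., 0]
    gx = sobel(L, axis=1, mode="reflect")
    gy = sobel(L, axis=0, mode="reflect")
    mag = np.hypot(gx, gy)
    theta = np.degrees(np.arctan2(gy, gx)) % 180.0
    bins = np.minimum((theta / (180.0 / cfg.V)).astype(np.intp), cfg.V - 1)
    return bins, mag


def _half_offsets(D: int) -> list[tuple[int, int]]:
    """One offset per unordered neighbour pair at Chebyshev distance D.

    Offsets (dy, dx) with max(|dy|, |dx|) == D and (dy, dx) lexicographically
    positive, so each pair is visited exactly once with the row-major-first
    pixel as the credited pixel.
    """
    offs = []
    for dy in range(0, D + 1):
        for dx in range(-D, D + 1):
            if max(abs(dy), abs(dx)) != D:
                continue
            if dy > 0 or (dy == 0 and dx > 0):
                offs.append((dy, dx))
    return offs


def _pair_maps(image: np.ndarray, cfg: CdhConfig, lab: np.ndarray | None = None):
    """Per-pixel gated colour-difference masses plus index maps.

    Returns (colour_mass, orientation_mass, colour_idx, ori_bins, magnitude)
    where the masses are credited to the row-major-first pixel of each pair.
    """
    img = validate_image(image)
    h, w = img.shape[:2]
    need = 2 * cfg.D + 1
    if h < need or w < need:
        raise ValueError(
            f"image {img.shape[:2]} smaller than the (2D+1)={need} neighbourhood")
    if lab is None:
        lab = rgb_to_lab(img)
    cidx = quantize_colour(lab, cfg)
    obins, mag = edge_orientation(lab, cfg)

    colour_mass = np.zeros((h, w))
    ori_mass = np.zeros((h, w))
    for dy, dx in _half_offsets(cfg.D):
        # p = first pixel region, q = shifted neighbour region
        py = slice(max(0, -dy), h - max(0, dy))
        px = slice(max(0, -dx), w - max(0, dx))
        qy = slice(max(0, dy), h + min(0, dy))
        qx = slice(max(0, dx), w + min(0, dx))
        diff = lab[qy, qx] - lab[py, px]
        dist = np.sqrt((diff ** 2).sum(axis=-1))
        same_ori = obins[py, px] == obins[qy, qx]
        same_col = cidx[py, px] == cidx[qy, qx]
        colour_mass[py, px] += np.where(same_ori, dist, 0.0)
        ori_mass[py, px] += np.where(same_col, dist, 0.0)
    return colour_mass, ori_mass, cidx, obins, mag


def cdh_descriptor(image: np.ndarray, cfg: CdhConfig | None = None,
                   lab: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Global CDH descriptor of an image.

    Returns a dict with ``h_color`` (length W), ``h_ori`` (length V) and
    their concatenation ``merged`` (length W + V).  A precomputed Lab image
    may be supplied via ``lab`` to skip the colour conversion.
    """
    cfg = cfg or CdhConfig()
    colour_mass, ori_mass, cidx, obins, _ = _pair_maps(image, cfg, lab=lab)
    h_color = np.bincount(cidx.ravel(), weights=colour_mass.ravel(),
                          minlength=cfg.W)
    h_ori = np.bincount(obins.ravel(), weights=ori_mass.ravel(),
                        minlength=cfg.V)
    return {"h_color": h_color, "h_ori": h_ori,
            "merged": np.concatenate([h_color, h_ori])}


def cdh_feature_map(image: np.ndarray, cfg: CdhConfig | None = None,
                    normalize: bool = True,
                    lab: np.ndarray | None = None) -> np.ndarray:
    """Image-shaped 3-channel CDH response map (the lane-2 network input).

    Channel 0: orientation-gated colour-difference mass per pixel.
    Channel 1: colour-gated colour-difference mass per pixel.
    Channel 2: L* gradient magnitude.
    With ``normalize`` each channel is divided by its maximum (all-zero
    channels pass through), giving values in [0, 1].  Zero parameters.
    """
    cfg = cfg or CdhConfig()
    colour_mass, ori_mass, _, _, mag = _pair_maps(image, cfg, lab=lab)
    fmap = np.stack([colour_mass, ori_mass, mag], axis=-1)
    if normalize:
        peaks = fmap.reshape(-1, 3).max(axis=0)
        peaks[peaks == 0] = 1.0
        fmap = fmap / peaks
    return fmap
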