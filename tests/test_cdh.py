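"""Colour-difference histogram: quantization, orientation, pair accumulation."""

import numpy as np
import pytest

from ccfmcaps import (CdhConfig, cdh_descriptor, cdh_feature_map,
                      edge_orientation, quantize_colour, rgb_to_lab,
                      toy_fixture)

SMALL_CFG = CdhConfig(W=8, V=4, D=1, lab_bins=(2, 2, 2))


# ---------------------------------------------------------------- oracles
def brute_quantize(lab, cfg):
    """Explicit per-pixel bin arithmetic."""
    nl, na, nb = cfg.lab_bins
    out = np.empty(lab.shape[:2], dtype=int)
    ranges = [(0.0, 100.0, nl), (-128.0, 127.0, na), (-128.0, 127.0, nb)]
    for (y, x), _ in np.ndenumerate(lab[..., 0]):
        bins = []
        for ch, (lo, hi, n) in enumerate(ranges):
            v = min(max(lab[y, x, ch], lo), hi)
            bins.append(min(int((v - lo) / (hi - lo) * n), n - 1))
        out[y, x] = bins[0] * na * nb + bins[1] * nb + bins[2]
    return out


def brute_cdh(image, cfg):
    """Exhaustive enumeration over all unordered neighbour pairs.

    The colour-difference mass of a pair is credited to its row-major-first
    pixel; returns the histograms plus the per-pixel restriction of each.
    """
    lab = rgb_to_lab(image)
    cidx = brute_quantize(lab, cfg)
    obins, _ = edge_orientation(lab, cfg)
    h, w = cidx.shape
    hc, ho = np.zeros(cfg.W), np.zeros(cfg.V)
    map_c, map_o = np.zeros((h, w)), np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            for dy in range(-cfg.D, cfg.D + 1):
                for dx in range(-cfg.D, cfg.D + 1):
                    if max(abs(dy), abs(dx)) != cfg.D:
                        continue
                    y2, x2 = y + dy, x + dx
                    if not (0 <= y2 < h and 0 <= x2 < w):
                        continue
                    if (y2, x2) <= (y, x):  # count each pair once
                        continue
                    d = np.sqrt(((lab[y2, x2] - lab[y, x]) ** 2).sum())
                    if obins[y, x] == obins[y2, x2]:
                        hc[cidx[y, x]] += d
                        map_c[y, x] += d
                    if cidx[y, x] == cidx[y2, x2]:
                        ho[obins[y, x]] += d
                        map_o[y, x] += d
    return hc, ho, map_c, map_o


# ------------------------------------------------------------ Lab conversion
class TestRgbToLab:
    def test_black_and_white_references(self):
        lab = rgb_to_lab(np.zeros((3, 3, 3)))
        assert abs(lab[0, 0, 0]) < 1e-6
        assert np.allclose(lab[0, 0, 1:], 0, atol=1e-6)
        lab = rgb_to_lab(np.ones((3, 3, 3)))
        assert lab[0, 0, 0] == pytest.approx(100.0, abs=0.01)

    def test_mid_grey_lightness_matches_hand_arithmetic(self):
        # sRGB 0.5 -> linear ((0.5+0.055)/1.055)^2.4 -> L* = 116 Y^(1/3) - 16
        y_lin = ((0.5 + 0.055) / 1.055) ** 2.4
        expected_L = 116.0 * y_lin ** (1.0 / 3.0) - 16.0
        lab = rgb_to_lab(np.full((2, 2, 3), 0.5))
        assert lab[0, 0, 0] == pytest.approx(expected_L, abs=0.05)
        assert expected_L == pytest.approx(53.39, abs=0.01)

    def test_grayscale_replicated(self):
        lab = rgb_to_lab(toy_fixture("step_edge"))
        assert lab.shape == (8, 8, 3)
        assert np.allclose(lab[..., 1:], 0, atol=0.01)  # achromatic


# ------------------------------------------------------------- quantization
class TestQuantizeColour:
    def test_constant_image_single_index(self):
        lab = rgb_to_lab(toy_fixture("constant"))
        assert len(np.unique(quantize_colour(lab))) == 1

    def test_black_white_distinct(self):
        img = np.zeros((2, 2, 3))
        img[:, 1] = 1.0
        idx = quantize_colour(rgb_to_lab(img), SMALL_CFG)
        assert idx[0, 0] != idx[0, 1]

    def test_matches_explicit_bin_arithmetic(self, rng):
        lab = np.stack([rng.uniform(0, 100, (4, 4)),
                        rng.uniform(-128, 127, (4, 4)),
                        rng.uniform(-128, 127, (4, 4))], axis=-1)
        for cfg in (CdhConfig(), SMALL_CFG):
            np.testing.assert_array_equal(quantize_colour(lab, cfg),
                                          brute_quantize(lab, cfg))

    def test_indices_in_range(self, rng):
        lab = rgb_to_lab(rng.random((6, 6, 3)))
        idx = quantize_colour(lab)
        assert idx.min() >= 0 and idx.max() < 72

    def test_bins_must_factorize(self):
        with pytest.raises(ValueError, match="factorize"):
            CdhConfig(W=72, lab_bins=(8, 3, 2))


# -------------------------------------------------------- edge orientation
class TestEdgeOrientation:
    def test_constant_image_zero_everything(self):
        bins, mag = edge_orientation(rgb_to_lab(toy_fixture("constant")))
        assert not bins.any() and not mag.any()

    def test_vertical_step_edge_bin_zero(self):
        # gradient along x => angle 0 from the x-axis => first bin
        bins, mag = edge_orientation(rgb_to_lab(toy_fixture("step_edge")),
                                     SMALL_CFG)
        col = slice(3, 5)  # columns astride the step
        assert (bins[:, col] == 0).all()
        assert (mag[:, col] > 0).all()

    def test_rotated_edge_lands_in_ninety_degree_bin(self):
        img = toy_fixture("step_edge").T  # horizontal edge: gradient along y
        bins, mag = edge_orientation(rgb_to_lab(img), SMALL_CFG)
        expect = int(90.0 // (180.0 / SMALL_CFG.V))
        row = slice(3, 5)
        assert (bins[row, :] == expect).all()
        assert (mag[row, :] > 0).all()

    def test_bins_within_range(self, rng):
        bins, mag = edge_orientation(rgb_to_lab(rng.random((6, 6, 3))))
        assert bins.min() >= 0 and bins.max() < 18
        assert (mag >= 0).all()


# ---------------------------------------------------------- the descriptor
class TestCdhDescriptor:
    def test_standard_dimensionality_is_ninety(self, rng):
        desc = cdh_descriptor(rng.random((8, 8, 3)), CdhConfig(W=72, V=18))
        assert desc["merged"].shape == (90,)
        assert desc["h_color"].shape == (72,) and desc["h_ori"].shape == (18,)

    def test_constant_image_all_zero(self):
        desc = cdh_descriptor(toy_fixture("constant"))
        assert not desc["merged"].any()

    def test_two_colour_toy_matches_brute_force(self):
        img = toy_fixture("two_colour_4x4")
        desc = cdh_descriptor(img, SMALL_CFG)
        hc, ho, _, _ = brute_cdh(img, SMALL_CFG)
        np.testing.assert_allclose(desc["h_color"], hc, atol=1e-10)
        np.testing.assert_allclose(desc["h_ori"], ho, atol=1e-10)
        assert desc["merged"].sum() > 0

    @pytest.mark.parametrize("seed", range(20))
    def test_random_fixtures_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        size = int(rng.integers(4, 9))
        img = rng.random((size, size, 3))
        cfg = SMALL_CFG if seed % 2 else CdhConfig()
        desc = cdh_descriptor(img, cfg)
        hc, ho, _, _ = brute_cdh(img, cfg)
        np.testing.assert_allclose(desc["h_color"], hc, atol=1e-9)
        np.testing.assert_allclose(desc["h_ori"], ho, atol=1e-9)

    def test_chebyshev_distance_two_matches_brute_force(self):
        rng = np.random.default_rng(5)
        img = rng.random((7, 7, 3))
        cfg = CdhConfig(W=8, V=4, D=2, lab_bins=(2, 2, 2))
        desc = cdh_descriptor(img, cfg)
        hc, ho, _, _ = brute_cdh(img, cfg)
        np.testing.assert_allclose(desc["h_color"], hc, atol=1e-9)
        np.testing.assert_allclose(desc["h_ori"], ho, atol=1e-9)

    def test_translation_by_whole_periods(self):
        tile = np.random.default_rng(3).random((2, 2, 3))
        periodic = np.tile(tile, (4, 4, 1))
        rolled = np.roll(periodic, (2, 2), axis=(0, 1))
        a = cdh_descriptor(periodic, SMALL_CFG)["merged"]
        b = cdh_descriptor(rolled, SMALL_CFG)["merged"]
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_entries_scale_linearly_with_lab_differences(self):
        img = toy_fixture("two_colour_4x4")
        lab = rgb_to_lab(img)
        # halving Lab leaves orientation bins unchanged (angles are scale
        # free) and the two colours still quantize apart, so every gated
        # accumulation — and hence every per-pixel mass and each
        # histogram's total — scales by exactly 0.5
        assert len(np.unique(quantize_colour(lab * 0.5, SMALL_CFG))) == 2
        base_map = cdh_feature_map(img, SMALL_CFG, normalize=False, lab=lab)
        half_map = cdh_feature_map(img, SMALL_CFG, normalize=False,
                                   lab=lab * 0.5)
        np.testing.assert_allclose(half_map, 0.5 * base_map, atol=1e-9)
        base = cdh_descriptor(img, SMALL_CFG, lab=lab)
        half = cdh_descriptor(img, SMALL_CFG, lab=lab * 0.5)
        assert half["h_color"].sum() == pytest.approx(
            0.5 * base["h_color"].sum())
        assert half["h_ori"].sum() == pytest.approx(0.5 * base["h_ori"].sum())

    def test_image_smaller_than_neighbourhood_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            cdh_descriptor(np.zeros((2, 2, 3)), SMALL_CFG)


# ---------------------------------------------------------- the lane input
class TestCdhFeatureMap:
    def test_constant_image_zero_map(self):
        fmap = cdh_feature_map(toy_fixture("constant"))
        assert fmap.shape == (8, 8, 3)
        assert not fmap.any()

    def test_shape_and_range(self, rng):
        img = rng.random((32, 32, 3))
        fmap = cdh_feature_map(img)
        assert fmap.shape == (32, 32, 3)
        assert fmap.min() >= 0 and fmap.max() <= 1.0

    def test_per_pixel_equality_with_brute_force(self):
        img = toy_fixture("two_colour_4x4")
        fmap = cdh_feature_map(img, SMALL_CFG, normalize=False)
        _, _, map_c, map_o = brute_cdh(img, SMALL_CFG)
        np.testing.assert_allclose(fmap[..., 0], map_c, atol=1e-10)
        np.testing.assert_allclose(fmap[..., 1], map_o, atol=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_map_conserves_histogram_totals(self, seed):
        img = np.random.default_rng(seed).random((6, 6, 3))
        fmap = cdh_feature_map(img, SMALL_CFG, normalize=False)
        desc = cdh_descriptor(img, SMALL_CFG)
        assert fmap[..., 0].sum() == pytest.approx(desc["h_color"].sum())
        assert fmap[..., 1].sum() == pytest.approx(desc["h_ori"].sum())

    def test_gradient_channel_is_magnitude(self, rng):
        img = rng.random((6, 6, 3))
        fmap = cdh_feature_map(img, normalize=False)
        _, mag = edge_orientation(rgb_to_lab(img))
        np.testing.assert_allclose(fmap[..., 2], mag)
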