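"""HSI conversion, positive-pixel counting and slide-level stain summaries."""

import numpy as np
import pytest
import scipy.stats

from lfbmil.config import ConfigError, DARK_BLUE, LIGHT_BLUE, HueRangeParams
from lfbmil.stain import (
    SlideStainSummary,
    TilePixelCounts,
    compare_groups,
    count_positive,
    kde2d,
    rgb_to_hsi,
    summarize_slide,
    tile_counts,
)


class TestRgbToHsi:
    @pytest.mark.parametrize("rgb,h,s,i", [
        ((0, 0, 255), 240.0, 1.0, 85.0),   # pure blue: theta=120, B>G -> 240
        ((255, 0, 0), 0.0, 1.0, 85.0),
        ((0, 255, 0), 120.0, 1.0, 85.0),
    ])
    def test_primary_colors(self, rgb, h, s, i):
        hue, sat, inten = rgb_to_hsi(np.array(rgb))
        assert hue == pytest.approx(h, abs=1e-9)
        assert sat == pytest.approx(s)
        assert inten == pytest.approx(i)

    def test_achromatic_hue_undefined(self):
        hue, sat, inten = rgb_to_hsi(np.array([100, 100, 100]))
        assert np.isnan(hue) and sat == 0.0 and inten == 100.0
        hue, sat, _ = rgb_to_hsi(np.array([0, 0, 0]))
        assert np.isnan(hue) and sat == 0.0

    def test_vectorized_matches_per_pixel(self, rng):
        img = rng.integers(0, 256, size=(5, 7, 3))
        h_img, s_img, i_img = rgb_to_hsi(img)
        for y in range(5):
            for x in range(7):
                h, s, i = rgb_to_hsi(img[y, x])
                np.testing.assert_allclose(
                    [s, i], [s_img[y, x], i_img[y, x]], atol=1e-12)
                if np.isnan(h):
                    assert np.isnan(h_img[y, x])
                else:
                    assert h == pytest.approx(h_img[y, x])


class TestCountPositive:
    def test_uniform_blue_tile_fully_dark(self):
        tile = np.zeros((256, 256, 3), dtype=np.uint8)
        tile[..., 2] = 255  # I = 85 < 120: dark band
        assert count_positive(tile, DARK_BLUE) == 256 * 256
        assert count_positive(tile, LIGHT_BLUE) == 0

    def test_grey_tile_never_positive(self):
        tile = np.full((64, 64, 3), 128, dtype=np.uint8)
        assert count_positive(tile, DARK_BLUE) == 0

    def test_half_blue_half_red(self):
        tile = np.zeros((256, 256, 3), dtype=np.uint8)
        tile[:, :128, 2] = 255
        tile[:, 128:, 0] = 255
        assert count_positive(tile, DARK_BLUE) == 256 * 128

    def test_scaling_preserves_hue_and_saturation_exactly(self, rng):
        """Multiplying RGB by c in (0,1] leaves H and S unchanged; only the
        intensity gates can change band membership."""
        img = (2 * rng.integers(10, 128, size=(32, 32, 3))).astype(np.uint8)  # even values
        h0, s0, _ = rgb_to_hsi(img)
        scaled = (img // 2).astype(np.uint8)  # exact c = 0.5
        h1, s1, i1 = rgb_to_hsi(scaled)
        np.testing.assert_array_equal(np.isnan(h0), np.isnan(h1))
        np.testing.assert_allclose(h0[~np.isnan(h0)], h1[~np.isnan(h1)], rtol=0, atol=1e-12)
        np.testing.assert_allclose(s0, s1, rtol=0, atol=1e-12)
        # a hue band with open intensity gates counts identically
        wide = HueRangeParams(240.0, 80.0, 0.15, 0.0, 256.0)
        assert count_positive(img, wide) == count_positive(scaled, wide)


class TestTileCounts:
    def test_ratio(self):
        c = TilePixelCounts("d", 0, dark_count=200, light_count=100)
        assert c.ratio == 2.0

    def test_ratio_undefined_when_no_light(self):
        c = TilePixelCounts("d", 0, dark_count=50, light_count=0)
        assert c.ratio is None and c.dark_count == 50

    def test_overlapping_bands_rejected(self):
        overlapping = HueRangeParams(240.0, 80.0, 0.15, 100.0, 200.0)
        with pytest.raises(ConfigError):
            tile_counts(np.zeros((4, 4, 3), dtype=np.uint8), DARK_BLUE, overlapping)


class TestSummarizeSlide:
    def test_zero_dark_tiles_dropped(self):
        counts = [TilePixelCounts("d", 0, 10, 5), TilePixelCounts("d", 1, 0, 7),
                  TilePixelCounts("d", 2, 30, 10)]
        s = summarize_slide(counts, donor_id="d")
        assert s.median_dark == 20.0
        assert s.median_ratio == pytest.approx(2.5)  # median of {2.0, 3.0}
        assert s.n_tiles_used == 2 and s.n_tiles_dropped == 1

    def test_single_retained_tile(self):
        s = summarize_slide([TilePixelCounts("d", 0, 12, 4)])
        assert s.median_dark == 12.0 and s.median_ratio == 3.0

    def test_all_dropped_flagged_missing(self):
        s = summarize_slide([TilePixelCounts("d", i, 0, 5) for i in range(4)])
        assert s.missing and s.n_tiles_dropped == 4


class TestCompareGroups:
    def test_identical_groups(self):
        res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["t"] == pytest.approx(0.0) and res["p"] == pytest.approx(1.0)

    def test_welch_closed_form(self):
        # groups {1,2,3} vs {4,5,6}: t = -3 / sqrt(1/3 + 1/3)
        res = compare_groups([1, 2, 3], [4, 5, 6])
        assert res["t"] == pytest.approx(-3.674, abs=1e-3)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [2.0, 3.0])


class TestKde2d:
    def test_density_integrates_to_one(self, rng):
        pts = rng.normal(size=(100, 2))
        res = kde2d(pts, grid_size=128)
        dx = res["x"][1] - res["x"][0]
        dy = res["y"][1] - res["y"][0]
        assert res["density"].sum() * dx * dy == pytest.approx(1.0, abs=0.01)

    def test_mirrored_data_mirrors_density(self, rng):
        pts = rng.normal(size=(50, 2))
        a = kde2d(pts, grid_size=64)
        b = kde2d(pts * np.array([-1.0, 1.0]), grid_size=64)
        np.testing.assert_allclose(a["density"], b["density"][::-1, :], atol=1e-12)

    def test_mode_near_cluster_mean(self, rng):
        center = np.array([3.0, -1.0])
        pts = center + 0.05 * rng.normal(size=(40, 2))
        res = kde2d(pts, grid_size=64, bandwidth=(0.1, 0.1),
                    limits=(0.0, 6.0, -4.0, 2.0))
        ix, iy = np.unravel_index(res["density"].argmax(), res["density"].shape)
        cell = max(res["x"][1] - res["x"][0], res["y"][1] - res["y"][0])
        assert abs(res["x"][ix] - pts[:, 0].mean()) <= cell
        assert abs(res["y"][iy] - pts[:, 1].mean()) <= cell

    def test_degenerate_axis_rejected(self):
        pts = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError):
            kde2d(pts)
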