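"""Tissue segmentation, tiling and feature extraction."""

import numpy as np
import pytest

from lfbmil.config import TilingConfig
from lfbmil.tiling import (
    FeatureBag,
    HandcraftedExtractor,
    build_bag,
    extract_features,
    load_bags,
    save_bags,
    segment_tissue,
    tile,
)


def _tissue_image(h, w, color=(200, 120, 140)):
    img = np.full((h, w, 3), 255, dtype=np.uint8)
    img[:] = color
    return img


class TestSegmentTissue:
    def test_all_white_gives_empty_mask(self):
        img = np.full((64, 64, 3), 255, dtype=np.uint8)
        assert segment_tissue(img).sum() == 0

    def test_covers_generated_tissue(self, example_slide):
        mask = segment_tissue(example_slide.image)
        tissue = example_slide.region_mask > 0
        coverage = (mask & tissue).sum() / tissue.sum()
        assert coverage >= 0.99

    def test_two_blobs_both_retained(self):
        img = np.full((128, 128, 3), 255, dtype=np.uint8)
        img[10:40, 10:40] = (200, 120, 140)
        img[80:110, 80:110] = (120, 140, 200)
        mask = segment_tissue(img, median_disk=0)
        assert mask[20, 20] and mask[95, 95]
        assert not mask[60, 60]

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            segment_tissue(np.empty((0, 0, 3), dtype=np.uint8))


class TestTile:
    def test_exact_division(self):
        img = _tissue_image(512, 512)
        grid = tile(img, np.ones((512, 512), dtype=bool))
        assert len(grid) == 4

    def test_partial_tiles_dropped(self):
        grid = tile(_tissue_image(700, 300), np.ones((700, 300), dtype=bool))
        assert len(grid) == 2  # 2x1 grid, remainders dropped

    def test_min_tissue_filter(self):
        mask = np.zeros((512, 512), dtype=bool)
        mask[:, :256] = True  # tissue only in the left half
        grid = tile(_tissue_image(512, 512), mask, min_tissue=0.5)
        assert len(grid) == 2
        assert all(c == 0 for c in grid.tiles[:, 1])

    def test_row_major_order_and_bounds(self):
        grid = tile(_tissue_image(768, 768), np.ones((768, 768), dtype=bool))
        assert len(grid) == 9
        rows_cols = [tuple(t[:2]) for t in grid.tiles]
        assert rows_cols == sorted(rows_cols)
        assert (grid.tiles[:, 2] + grid.tile_size <= 768).all()

    def test_oversized_tile_rejected(self):
        with pytest.raises(ValueError):
            tile(_tissue_image(128, 128), np.ones((128, 128), dtype=bool), tile_size=256)


class TestExtractor:
    def test_uniform_grey_tile(self):
        ex = HandcraftedExtractor(dim=64)
        vec = ex(np.full((256, 256, 3), 128, dtype=np.uint8))
        hue_hist = vec[:ex.N_HUE]
        assert np.all(hue_hist == 0)  # saturation gate blocks achromatic pixels
        means = vec[ex.N_HUE:ex.N_HUE + 3]
        assert means == pytest.approx([128 / 255] * 3)
        sds = vec[ex.N_HUE + 3:ex.N_HUE + 6]
        assert sds == pytest.approx([0.0] * 3)

    def test_deterministic(self, rng):
        ex = HandcraftedExtractor(dim=128)
        t = rng.integers(0, 256, size=(64, 64, 3)).astype(np.uint8)
        np.testing.assert_array_equal(ex(t), ex(t))

    def test_zero_padding(self):
        ex = HandcraftedExtractor(dim=256)
        vec = ex(np.full((32, 32, 3), 100, dtype=np.uint8))
        assert vec.shape == (256,)
        assert np.all(vec[ex.BASE_DIM:] == 0)

    def test_bag_aligned_with_grid(self, example_slide):
        cfg = TilingConfig(feature_dim=128)
        bag = build_bag(example_slide.image, cfg, donor_id="d")
        assert bag is not None
        mask = segment_tissue(example_slide.image)
        grid = tile(example_slide.image, mask)
        assert len(bag.features) == len(grid)
        np.testing.assert_array_equal(bag.coords, grid.tiles)

    def test_translation_by_tile_size_permutes_features(self, rng):
        """Shifting content by exactly one tile permutes tile feature rows."""
        ex = HandcraftedExtractor(dim=64)
        img = rng.integers(0, 256, size=(512, 512, 3)).astype(np.uint8)
        rolled = np.roll(img, 256, axis=1)
        full = np.ones((512, 512), dtype=bool)
        bag_a = extract_features(img, tile(img, full), ex)
        bag_b = extract_features(rolled, tile(rolled, full), ex)
        # tiles (r, 0) of the original appear as (r, 1) after the roll
        np.testing.assert_allclose(bag_a.features[0], bag_b.features[1])
        np.testing.assert_allclose(bag_a.features[1], bag_b.features[0])

    def test_dimension_mismatch_rejected(self, rng):
        class Bad:
            dim = 32
            name = "bad"
            def __call__(self, t):
                return np.zeros(16)
        img = _tissue_image(256, 256)
        grid = tile(img, np.ones((256, 256), dtype=bool))
        with pytest.raises(ValueError):
            extract_features(img, grid, Bad())


class TestBagIO:
    def test_hdf5_roundtrip(self, rng, tmp_path):
        bags = [FeatureBag(donor_id=f"d{i}",
                           features=rng.normal(size=(4, 16)),
                           coords=np.arange(16).reshape(4, 4))
                for i in range(3)]
        save_bags(bags, tmp_path / "bags.h5")
        loaded = load_bags(tmp_path / "bags.h5")
        assert [b.donor_id for b in loaded] == ["d0", "d1", "d2"]
        np.testing.assert_allclose(loaded[1].features, bags[1].features)
        np.testing.assert_array_equal(loaded[2].coords, bags[2].coords)

    def test_nonfinite_features_rejected(self):
        with pytest.raises(ValueError):
            FeatureBag(donor_id="d", features=np.array([[np.inf]]),
                       coords=np.zeros((1, 4), dtype=int))
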