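"""Tissue segmentation, 256x256 tiling, and per-tile feature extraction.

Slides are segmented by thresholding HSV saturation after median smoothing
(white background is unsaturated, stained tissue is not), tiled into
non-overlapping 256x256 patches anchored at the image origin, and each kept
tile is mapped to a fixed-length feature vector.  The default extractor is
hand-crafted and CPU-cheap — a saturation-gated hue histogram, per-channel
intensity moments, an intensity histogram and gradient-magnitude statistics,
zero-padded to the configured dimension — and is deterministic; any
callable with a declared output dimension (e.g. a pretrained CNN trunk) can
be plugged in instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol

import h5py
import numpy as np
from skimage.color import rgb2hsv
from skimage.filters import median as median_filter
from skimage.morphology import disk

from .config import TilingConfig
from .stain import rgb_to_hsi

logger = logging.getLogger(__name__)

__all__ = [
    "TileGrid",
    "FeatureBag",
    "FeatureExtractor",
    "HandcraftedExtractor",
    "segment_tissue",
    "tile",
    "extract_features",
    "save_bags",
    "load_bags",
]


@dataclass
class TileGrid:
    """Non-overlapping tile grid over one slide.

    ``tiles`` rows are (row, col, x0, y0) with half-open pixel intervals
    [y0, y0+tile_size) x [x0, x0+tile_size), in row-major order.
    """

    tile_size: int
    tiles: np.ndarray            # (K, 4) int: row, col, x0, y0
    tissue_fraction: np.ndarray  # (K,) float

    def __len__(self) -> int:
        return len(self.tiles)


@dataclass
class FeatureBag:
    """Per-slide bag of tile feature vectors aligned with tile coordinates."""

    donor_id: str
    features: np.ndarray  # (K, D)
    coords: np.ndarray    # (K, 4) row, col, x0, y0
    extractor_id: str = "handcrafted-v1"

    def __post_init__(self) -> None:
        if len(self.features) != len(self.coords):
            raise ValueError("features and coords misaligned")
        if len(self.features) < 1:
            raise ValueError("feature bag must contain at least one tile")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("non-finite feature values")


class FeatureExtractor(Protocol):
    dim: int
    name: str

    def __call__(self, tile_rgb: np.ndarray) -> np.ndarray: ...


def segment_tissue(image: np.ndarray, saturation_threshold: float = 0.05,
                   median_disk: int = 2) -> np.ndarray:
    """Foreground mask: median-smoothed HSV saturation above threshold.

    Disconnected tissue pieces are all retained.  A zero-tissue result is
    returned as an empty mask and logged so the caller can skip the slide.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    sat = rgb2hsv(image)[..., 1]
    if median_disk > 0:
        sat = median_filter(sat, footprint=disk(median_disk))
    mask = sat > saturation_threshold
    if not mask.any():
        logger.warning("segment_tissue: no tissue found; slide should be skipped")
    return mask


def tile(image: np.ndarray, mask: np.ndarray, tile_size: int = 256,
         min_tissue: float = 0.5) -> TileGrid:
    """Grid the slide into tiles and keep those with enough tissue.

    The grid is anchored at (0, 0); partial tiles at the right/bottom edges
    are dropped; a tile is kept iff its tissue fraction is >= ``min_tissue``.
    """
    h, w = mask.shape
    if tile_size > h or tile_size > w:
        raise ValueError(f"tile_size {tile_size} exceeds image dimensions {h}x{w}")
    n_rows, n_cols = h // tile_size, w // tile_size
    tiles, fractions = [], []
    for r in range(n_rows):
        for c in range(n_cols):
            y0, x0 = r * tile_size, c * tile_size
            frac = mask[y0:y0 + tile_size, x0:x0 + tile_size].mean()
            if frac >= min_tissue:
                tiles.append((r, c, x0, y0))
                fractions.append(frac)
    return TileGrid(
        tile_size=tile_size,
        tiles=np.asarray(tiles, dtype=int).reshape(-1, 4),
        tissue_fraction=np.asarray(fractions, dtype=float),
    )


class HandcraftedExtractor:
    """Deterministic hand-crafted tile features, zero-padded to ``dim``.

    Layout: 24-bin hue histogram over [0, 360) gated at saturation >= 0.15
    (normalized by total pixel count, so unsaturated tiles give near-zero
    bins), per-channel mean and s.d. (scaled to [0, 1]), a 16-bin intensity
    histogram, and gradient-magnitude mean / s.d. / 90th percentile of the
    intensity channel.
    """

    N_HUE, N_INT = 24, 16
    BASE_DIM = N_HUE + 6 + N_INT + 3
    name = "handcrafted-v1"

    def __init__(self, dim: int = 1024, saturation_gate: float = 0.15):
        if dim < self.BASE_DIM:
            raise ValueError(f"dim must be >= {self.BASE_DIM}")
        self.dim = dim
        self.saturation_gate = saturation_gate

    def __call__(self, tile_rgb: np.ndarray) -> np.ndarray:
        arr = np.asarray(tile_rgb, dtype=np.float64)
        n_px = arr.shape[0] * arr.shape[1]
        hue, sat, intensity = rgb_to_hsi(arr)

        gated = np.isfinite(hue) & (sat >= self.saturation_gate)
        hue_hist = np.histogram(hue[gated], bins=self.N_HUE, range=(0.0, 360.0))[0] / n_px

        means = arr.reshape(-1, 3).mean(axis=0) / 255.0
        sds = arr.reshape(-1, 3).std(axis=0) / 255.0

        int_hist = np.histogram(intensity, bins=self.N_INT, range=(0.0, 256.0))[0] / n_px

        gy, gx = np.gradient(intensity)
        gmag = np.hypot(gy, gx) / 255.0
        grad = np.array([gmag.mean(), gmag.std(), np.percentile(gmag, 90)])

        vec = np.concatenate([hue_hist, means, sds, int_hist, grad])
        out = np.zeros(self.dim)
        out[: len(vec)] = vec
        return out


def extract_features(image: np.ndarray, grid: TileGrid,
                     extractor: FeatureExtractor | None = None,
                     donor_id: str = "") -> FeatureBag:
    """One feature vector per kept tile, rows aligned with ``grid.tiles``."""
    if extractor is None:
        extractor = HandcraftedExtractor()
    ts = grid.tile_size
    feats = np.empty((len(grid), extractor.dim))
    for i, (_, _, x0, y0) in enumerate(grid.tiles):
        vec = extractor(image[y0:y0 + ts, x0:x0 + ts])
        if vec.shape != (extractor.dim,):
            raise ValueError(
                f"extractor returned shape {vec.shape}, declared dim {extractor.dim}")
        feats[i] = vec
    return FeatureBag(donor_id=donor_id, features=feats,
                      coords=grid.tiles.copy(), extractor_id=extractor.name)


def build_bag(image: np.ndarray, config: TilingConfig,
              extractor: FeatureExtractor | None = None,
              donor_id: str = "") -> FeatureBag | None:
    """Segment, tile and featurize one slide; None when no tile passes."""
    mask = segment_tissue(image, config.saturation_threshold, config.median_disk)
    grid = tile(image, mask, config.tile_size, config.min_tissue)
    if len(grid) == 0:
        logger.warning("slide %s: no tiles with sufficient tissue; skipped", donor_id)
        return None
    if extractor is None:
        extractor = HandcraftedExtractor(dim=config.feature_dim)
    return extract_features(image, grid, extractor, donor_id=donor_id)


def save_bags(bags: list[FeatureBag], path: str | Path) -> None:
    """Persist bags to HDF5, one group per slide."""
    with h5py.File(path, "w") as f:
        for bag in bags:
            grp = f.create_group(bag.donor_id)
            grp.create_dataset("features", data=bag.features)
            grp.create_dataset("coords", data=bag.coords)
            grp.attrs["extractor_id"] = bag.extractor_id


def load_bags(path: str | Path) -> list[FeatureBag]:
    bags = []
    with h5py.File(path, "r") as f:
        for donor_id in sorted(f.keys()):
            grp = f[donor_id]
            bags.append(FeatureBag(
                donor_id=donor_id,
                features=np.asarray(grp["features"]),
                coords=np.asarray(grp["coords"]),
                extractor_id=str(grp.attrs.get("extractor_id", "")),
            ))
    return bags
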