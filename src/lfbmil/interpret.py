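"""Attention interpretation: z-scores, heatmaps, region statistics, top tiles.

Raw per-tile attention is z-transformed (per slide by default) so slides
with different tile counts are comparable; tiles are assigned to annotated
regions (grey or white matter) by the region label at their center pixel,
and per-slide region medians are compared across slides with a paired
t-test.  The tiles with the highest raw attention are the input to the
downstream stain quantification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.stats
import matplotlib

__all__ = [
    "AttentionMap",
    "z_transform",
    "render_heatmap",
    "RegionAttentionSummary",
    "region_attention",
    "top_k_tiles",
]

BACKGROUND, GREY_MATTER, WHITE_MATTER = 0, 1, 2


def z_transform(scores: Sequence[float]) -> np.ndarray:
    """Z-scores with the sample standard deviation (denominator K-1).

    A single score or constant scores transform to all zeros.
    """
    a = np.asarray(scores, dtype=float)
    if a.size == 0:
        raise ValueError("no scores")
    if a.size == 1 or np.all(a == a[0]):
        return np.zeros_like(a)
    return (a - a.mean()) / a.std(ddof=1)


@dataclass
class AttentionMap:
    """Per-tile attention for one slide, raw and z-transformed."""

    donor_id: str
    attention: np.ndarray  # (K,) raw softmax weights
    coords: np.ndarray     # (K, 4) row, col, x0, y0
    tile_size: int = 256

    def __post_init__(self) -> None:
        if len(self.attention) != len(self.coords):
            raise ValueError("attention and coords misaligned")

    @property
    def z_scores(self) -> np.ndarray:
        return z_transform(self.attention)


def render_heatmap(amap: AttentionMap, image: np.ndarray, alpha: float = 0.5) -> dict:
    """Alpha-blend a blue-to-red attention overlay onto the slide.

    Attention is min-max normalized per slide (constant attention maps to
    mid-scale) and passed through a blue->red colormap; only tile footprints
    are tinted.  Returns the overlay plus colorbar metadata.
    """
    h, w = image.shape[:2]
    ts = amap.tile_size
    if (amap.coords[:, 3].max() + ts > h) or (amap.coords[:, 2].max() + ts > w):
        raise ValueError("tile coordinates fall outside the image")
    a = amap.attention.astype(float)
    span = a.max() - a.min()
    norm = (a - a.min()) / span if span > 0 else np.full_like(a, 0.5)
    colors = (matplotlib.colormaps["coolwarm"](norm)[:, :3] * 255).astype(np.float64)
    overlay = image.astype(np.float64).copy()
    for (row, col, x0, y0), color in zip(amap.coords, colors):
        patch = overlay[y0:y0 + ts, x0:x0 + ts]
        overlay[y0:y0 + ts, x0:x0 + ts] = (1 - alpha) * patch + alpha * color
    return {
        "overlay": np.clip(np.round(overlay), 0, 255).astype(np.uint8),
        "colormap": "coolwarm",
        "vmin": float(a.min()),
        "vmax": float(a.max()),
    }


@dataclass
class RegionAttentionSummary:
    """Per-slide median attention z-score by region, with the paired test."""

    slide_ids: list[str]
    wm_median: np.ndarray
    gm_median: np.ndarray
    t_statistic: float
    p_value: float
    n_excluded: int


def _tile_region_labels(amap: AttentionMap, region_mask: np.ndarray) -> np.ndarray:
    """Region label at each tile's center pixel."""
    half = amap.tile_size // 2
    ys = amap.coords[:, 3] + half
    xs = amap.coords[:, 2] + half
    return region_mask[ys, xs]


def region_attention(maps: Sequence[AttentionMap],
                     region_masks: Sequence[np.ndarray]) -> RegionAttentionSummary:
    """Median tile z-attention per region per slide; paired t-test WM vs GM.

    Tiles are assigned by center-pixel region; tiles centered on background
    are excluded.  Slides lacking tiles in either region are excluded from
    the paired test and counted.
    """
    slide_ids, wm_meds, gm_meds = [], [], []
    n_excluded = 0
    for amap, mask in zip(maps, region_masks):
        if mask.shape[0] < amap.coords[:, 3].max() + amap.tile_size:
            raise ValueError(f"mask misaligned for slide {amap.donor_id}")
        regions = _tile_region_labels(amap, mask)
        z = amap.z_scores
        wm = z[regions == WHITE_MATTER]
        gm = z[regions == GREY_MATTER]
        if len(wm) == 0 or len(gm) == 0:
            n_excluded += 1
            continue
        slide_ids.append(amap.donor_id)
        wm_meds.append(float(np.median(wm)))
        gm_meds.append(float(np.median(gm)))
    if not slide_ids:
        raise ValueError("no slide has tiles in both regions")
    wm_arr, gm_arr = np.asarray(wm_meds), np.asarray(gm_meds)
    diffs = wm_arr - gm_arr
    if np.allclose(diffs, diffs[0]) and len(diffs) > 1 and diffs.std(ddof=1) == 0:
        t, p = (0.0, 1.0) if diffs[0] == 0 else (np.inf * np.sign(diffs[0]), 0.0)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t, p = scipy.stats.ttest_rel(wm_arr, gm_arr)
    return RegionAttentionSummary(
        slide_ids=slide_ids, wm_median=wm_arr, gm_median=gm_arr,
        t_statistic=float(t), p_value=float(p), n_excluded=n_excluded,
    )


def top_k_tiles(amap: AttentionMap, k: int = 100) -> np.ndarray:
    """Indices of the k tiles with the highest raw attention.

    Descending attention, ties broken by ascending row-major tile index;
    when the slide has fewer than k tiles, all are returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(amap.attention)
    # stable sort on negated attention preserves ascending index within ties
    order = np.argsort(-amap.attention, kind="stable")
    if n < k:
        warnings.warn(f"slide {amap.donor_id}: only {n} tiles available for top-{k}")
        return order
    return order[:k]
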