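"""HSI hue-range positive-pixel counting for LFB-like myelin staining.

Luxol fast blue colors CNS myelin dark blue; myelin pallor shows up as a
loss of dark-blue pixels.  Staining is quantified by counting pixels whose
hue falls in a configured blue band, split by intensity into a "dark" and a
"light" sub-band.  The dark count measures staining intensity; the
dark/light ratio normalizes for per-slide variation in overall stain uptake,
because multiplying an RGB image by a gain changes intensity but leaves hue
and saturation untouched.

The RGB -> HSI transform is the classic arccos formulation:

    I = (R + G + B) / 3
    S = 1 - 3 min(R, G, B) / (R + G + B)        (S = 0 for pure black)
    H = theta          if B <= G
      = 360 - theta    if B >  G
    theta = arccos( ((R-G) + (R-B)) / 2 / sqrt((R-G)^2 + (R-B)(G-B)) )

Hue is undefined (returned as NaN) for achromatic pixels (S = 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.stats

from .config import ConfigError, DARK_BLUE, LIGHT_BLUE, HueRangeParams

__all__ = [
    "rgb_to_hsi",
    "circular_hue_distance",
    "count_positive",
    "TilePixelCounts",
    "tile_counts",
    "SlideStainSummary",
    "summarize_slide",
    "compare_groups",
    "kde2d",
]


def rgb_to_hsi(rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert 8-bit RGB to (H degrees, S in [0,1], I in [0,255]).

    Accepts a single pixel ``(3,)`` or an image ``(..., 3)``.  H is NaN where
    S = 0 (achromatic, including pure black).
    """
    arr = np.asarray(rgb, dtype=np.float64)
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    total = r + g + b
    intensity = total / 3.0

    with np.errstate(divide="ignore", invalid="ignore"):
        sat = np.where(total > 0, 1.0 - 3.0 * np.minimum(np.minimum(r, g), b) / total, 0.0)
        num = 0.5 * ((r - g) + (r - b))
        den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
        theta = np.degrees(np.arccos(np.clip(np.where(den > 0, num / den, 1.0), -1.0, 1.0)))
    hue = np.where(b > g, 360.0 - theta, theta)
    hue = np.where(sat > 0, hue, np.nan)
    return hue, sat, intensity


def circular_hue_distance(hue: np.ndarray, center: float) -> np.ndarray:
    """Shortest angular distance (degrees) from ``hue`` to ``center``."""
    d = np.abs(np.asarray(hue) - center) % 360.0
    return np.minimum(d, 360.0 - d)


def count_positive(tile: np.ndarray, params: HueRangeParams) -> int:
    """Number of pixels of an RGB tile inside a hue/saturation/intensity band.

    A pixel is positive when its circular hue distance to the band center is
    at most half the band width, saturation is at least ``saturation_min``,
    and intensity lies in ``[intensity_min, intensity_max)``.  Achromatic
    pixels are never positive.
    """
    hue, sat, intensity = rgb_to_hsi(tile)
    with np.errstate(invalid="ignore"):
        in_hue = circular_hue_distance(hue, params.hue_center) <= params.hue_width / 2.0
    mask = (
        np.isfinite(hue)
        & in_hue
        & (sat >= params.saturation_min)
        & (intensity >= params.intensity_min)
        & (intensity < params.intensity_max)
    )
    return int(mask.sum())


@dataclass
class TilePixelCounts:
    """Dark- and light-blue positive-pixel counts for one tile."""

    donor_id: str
    tile_index: int
    dark_count: int
    light_count: int

    @property
    def ratio(self) -> Optional[float]:
        """dark/light ratio; undefined (None) when light_count == 0."""
        if self.light_count == 0:
            return None
        return self.dark_count / self.light_count


def _bands_overlap(dark: HueRangeParams, light: HueRangeParams) -> bool:
    hue_gap = circular_hue_distance(np.array(dark.hue_center), light.hue_center)
    hue_overlap = hue_gap <= (dark.hue_width + light.hue_width) / 2.0
    int_overlap = dark.intensity_min < light.intensity_max and light.intensity_min < dark.intensity_max
    return bool(hue_overlap and int_overlap)


def tile_counts(
    tile: np.ndarray,
    dark: HueRangeParams = DARK_BLUE,
    light: HueRangeParams = LIGHT_BLUE,
    donor_id: str = "",
    tile_index: int = 0,
) -> TilePixelCounts:
    """Count dark- and light-band positive pixels in one tile.

    The two bands must be disjoint in hue x intensity space so no pixel can
    be both dark and light.
    """
    if _bands_overlap(dark, light):
        raise ConfigError("dark and light bands overlap in hue x intensity space")
    return TilePixelCounts(
        donor_id=donor_id,
        tile_index=tile_index,
        dark_count=count_positive(tile, dark),
        light_count=count_positive(tile, light),
    )


@dataclass
class SlideStainSummary:
    """Per-slide medians over retained top-attention tiles."""

    donor_id: str
    median_dark: Optional[float]
    median_ratio: Optional[float]
    n_tiles_used: int
    n_tiles_dropped: int

    @property
    def missing(self) -> bool:
        return self.median_dark is None


def summarize_slide(
    counts: Sequence[TilePixelCounts],
    donor_id: str = "",
    zero_positive_rule: str = "dark_only",
) -> SlideStainSummary:
    """Median dark count and dark/light ratio over a slide's top tiles.

    Outlier tiles with zero positive pixels are dropped before taking
    medians ("dark_only": zero dark pixels; "either_band": zero in either
    band).  The ratio median is over retained tiles with a defined ratio.
    """
    if zero_positive_rule == "dark_only":
        kept = [c for c in counts if c.dark_count > 0]
    else:
        kept = [c for c in counts if c.dark_count > 0 and c.light_count > 0]
    n_dropped = len(counts) - len(kept)
    if not kept:
        return SlideStainSummary(donor_id, None, None, 0, n_dropped)
    ratios = [c.ratio for c in kept if c.ratio is not None]
    return SlideStainSummary(
        donor_id=donor_id,
        median_dark=float(np.median([c.dark_count for c in kept])),
        median_ratio=float(np.median(ratios)) if ratios else None,
        n_tiles_used=len(kept),
        n_tiles_dropped=n_dropped,
    )


def compare_groups(values_a: Sequence[float], values_b: Sequence[float]) -> dict:
    """Welch two-sample t-test between two groups of slide-level medians."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 slides")
    t, p = scipy.stats.ttest_ind(a, b, equal_var=False)
    return {
        "t": float(t),
        "p": float(p),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "n_a": len(a),
        "n_b": len(b),
    }


def _nrd_bandwidth(x: np.ndarray) -> float:
    # Normal-reference rule per axis (Scott/Silverman family).
    sd = np.std(x, ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    if spread <= 0:
        raise ValueError("degenerate (zero-variance) axis for 2-D KDE")
    return 1.06 * spread * len(x) ** (-1 / 5)


def kde2d(
    points: np.ndarray,
    grid_size: int = 64,
    bandwidth: Optional[tuple[float, float]] = None,
    limits: Optional[tuple[float, float, float, float]] = None,
) -> dict:
    """Gaussian product-kernel 2-D density on a regular grid.

    Bandwidths default to the normal-reference rule per axis.  Returns the
    grid axes, the density surface (integrates to ~1 over a wide enough
    grid), and matplotlib-free contour metadata (levels at 25/50/75% of the
    max density).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if len(pts) < 5:
        raise ValueError("2-D KDE requires at least 5 points")
    hx = bandwidth[0] if bandwidth else _nrd_bandwidth(pts[:, 0])
    hy = bandwidth[1] if bandwidth else _nrd_bandwidth(pts[:, 1])
    if limits is None:
        limits = (
            pts[:, 0].min() - 3 * hx,
            pts[:, 0].max() + 3 * hx,
            pts[:, 1].min() - 3 * hy,
            pts[:, 1].max() + 3 * hy,
        )
    gx = np.linspace(limits[0], limits[1], grid_size)
    gy = np.linspace(limits[2], limits[3], grid_size)
    kx = scipy.stats.norm.pdf((gx[:, None] - pts[None, :, 0]) / hx) / hx  # (gx, n)
    ky = scipy.stats.norm.pdf((gy[:, None] - pts[None, :, 1]) / hy) / hy
    density = kx @ ky.T / len(pts)  # (gx, gy)
    peak = float(density.max())
    levels = [0.25 * peak, 0.5 * peak, 0.75 * peak]

    from skimage.measure import find_contours
    contours = []
    for level in levels:
        for poly in find_contours(density, level):
            # grid indices -> data coordinates
            xs = np.interp(poly[:, 0], np.arange(grid_size), gx)
            ys = np.interp(poly[:, 1], np.arange(grid_size), gy)
            contours.append({"level": float(level),
                             "vertices": np.column_stack([xs, ys])})
    return {
        "x": gx,
        "y": gy,
        "density": density,
        "bandwidth": (float(hx), float(hy)),
        "contour_levels": levels,
        "contours": contours,
    }
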