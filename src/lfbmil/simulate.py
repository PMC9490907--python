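"""Synthetic cohort and LFB-like slide generation with planted ground truth.

The generator emulates the statistical structure the analysis assumes, so
every downstream step can be tested for parameter recovery:

* a cohort of elderly brain donors whose true impairment state depends
  logistically on age, with Braak stage, ARTAG, CERAD and cerebrovascular
  disease positively associated with impairment, and cognitive measures
  (CDR, MMSE, clinical diagnosis) derived from the true state, then
  corrupted at rate ``label_noise`` and masked at rate ``missingness``;
* slide images with a grey-matter compartment (pink eosin-like background
  with dark nucleus dots) and a white-matter compartment (light-blue wash
  with short dark-blue fiber strokes).  White-matter dark-blue pixel
  density is ``base_density * (1 - effect_size)`` for truly impaired
  donors, applied to a random ``patchiness`` fraction of white-matter
  tiles; the whole image is multiplied by a per-slide stain gain
  ~ Normal(1, stain_gain_sd), emulating systemic staining variation across
  slides.

All distributions are artifact choices of this package, exposed through
:class:`~lfbmil.config.SimConfig`; real brain-bank cohorts come with no
generative model, so none of these defaults should be read as estimated
from data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.draw import line_aa

from .config import DARK_BLUE, ConfigError, SimConfig
from .labels import DonorRecord, cap_cdr
from .stain import count_positive

__all__ = [
    "SyntheticSlide",
    "generate_cohort",
    "generate_slide",
    "cohort_to_frame",
    "write_cohort_csv",
    "write_slide",
]

# Rendering palette (uint8 RGB).  The two blue tones sit inside the default
# dark/light hue bands so stain quantification is self-consistent with the
# generator; GM pink and nucleus purple sit outside the blue hue band.
_BACKGROUND = np.array([245, 245, 245], dtype=np.float64)
_GM_PINK = np.array([240, 185, 195], dtype=np.float64)
_WM_LIGHT_BLUE = np.array([150, 170, 225], dtype=np.float64)
_DARK_BLUE_FIBER = np.array([40, 50, 120], dtype=np.float64)
_NUCLEUS = np.array([80, 45, 80], dtype=np.float64)

_STROKE_LEN = 9  # px; short myelinated-fiber strokes

COHORT_COLUMNS = [
    "donor_id", "age", "sex", "cdr", "mmse", "clinical_dx",
    "braak", "cerad", "artag", "cvd", "region", "slide_path",
]


@dataclass
class SyntheticSlide:
    """One rendered slide with its ground truth."""

    image: np.ndarray            # (H, W, 3) uint8
    region_mask: np.ndarray      # (H, W) uint8: 0 background, 1 GM, 2 WM
    true_tile_density: np.ndarray  # (rows, cols) dark-blue pixel fraction per tile
    donor_id: str
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.region_mask.shape:
            raise ValueError("image and region mask dimensions differ")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(config: SimConfig) -> list[DonorRecord]:
    """Draw a synthetic donor cohort; deterministic under ``config.seed``."""
    rng = np.random.default_rng([config.seed, 101])
    n = config.n_donors
    age = rng.normal(config.age_mean, config.age_sd, size=n)

    # True impairment depends logistically on age, anchored so that a donor
    # of mean age has probability p_impaired.
    logit0 = np.log(config.p_impaired / (1.0 - config.p_impaired)) if 0 < config.p_impaired < 1 else (
        np.inf if config.p_impaired >= 1 else -np.inf)
    p_ci = _sigmoid(config.age_ci_slope * (age - config.age_mean) + logit0)
    true_ci = rng.random(n) < p_ci

    # Comorbid pathology, mildly enriched in impaired donors.
    braak = np.clip(np.round(rng.normal(2.2 + 0.8 * true_ci, 1.2)), 0, 6).astype(int)
    cerad = (rng.random(n) < (0.15 + 0.06 * true_ci)).astype(int)
    artag = (rng.random(n) < (0.22 + 0.12 * true_ci)).astype(int)
    cvd = (rng.random(n) < (0.18 + 0.18 * true_ci)).astype(int)
    sex = np.where(rng.random(n) < 0.54, "F", "M")

    # Recorded measures reflect the true state unless the donor's record is
    # corrupted (rate label_noise), in which case all measures contradict it.
    corrupted = rng.random(n) < config.label_noise
    recorded_ci = true_ci ^ corrupted

    records: list[DonorRecord] = []
    for i in range(n):
        if recorded_ci[i]:
            raw_cdr = rng.choice([0.5, 1.0, 2.0, 3.0, 4.0, 5.0],
                                 p=[0.35, 0.25, 0.15, 0.15, 0.06, 0.04])
            mmse = int(rng.integers(5, 25))       # <= 24
            dx = "impaired"
        else:
            raw_cdr = 0.0
            mmse = int(rng.integers(25, 31))      # 25..30
            dx = "not_impaired"
        cdr = cap_cdr(float(raw_cdr))
        miss = rng.random(3) < config.missingness
        records.append(DonorRecord(
            donor_id=f"D{i:04d}",
            age=float(age[i]),
            sex=str(sex[i]),
            cdr=None if miss[0] else cdr,
            mmse=None if miss[1] else mmse,
            clinical_dx=None if miss[2] else dx,
            braak=int(braak[i]),
            cerad=int(cerad[i]),
            artag=int(artag[i]),
            cvd=int(cvd[i]),
            true_state="CI" if true_ci[i] else "NCI",
        ))
    return records


def _compartment_masks(px: int, wm_fraction: float, rng: np.random.Generator,
                       two_pieces: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Tissue layout: elliptical piece(s), lower part white matter.

    The GM/WM boundary follows a wavy horizontal line placed so the
    white-matter share of tissue equals ``wm_fraction``.
    """
    yy, xx = np.mgrid[0:px, 0:px].astype(np.float64)
    if two_pieces:
        cys, cxs, ays, axs = [0.28, 0.72], [0.5, 0.5], [0.20, 0.20], [0.40, 0.40]
    else:
        cys, cxs, ays, axs = [0.5], [0.5], [0.40], [0.44]
    tissue = np.zeros((px, px), dtype=bool)
    for cy, cx, ay, ax in zip(cys, cxs, ays, axs):
        tissue |= ((yy - cy * px) / (ay * px)) ** 2 + ((xx - cx * px) / (ax * px)) ** 2 <= 1.0
    if not tissue.any():
        raise ConfigError("slide too small to contain tissue")

    wobble = 0.03 * px * np.sin(2 * np.pi * (xx / px) * rng.uniform(1.5, 3.0)
                                + rng.uniform(0, 2 * np.pi))
    # Choose the split row so the WM share of tissue matches wm_fraction.
    rows = np.nonzero(tissue.any(axis=1))[0]
    counts = tissue.sum(axis=1).astype(float)
    cum = np.cumsum(counts[::-1])[::-1]  # tissue pixels at or below each row
    target = wm_fraction * tissue.sum()
    split_row = rows[0] + int(np.searchsorted(-cum[rows[0]:rows[-1] + 1], -target))
    wm = tissue & (yy + wobble >= split_row)
    if not wm.any() or not (tissue & ~wm).any():
        raise ConfigError("slide too small to contain both compartments")
    return tissue, wm


def _draw_strokes(image: np.ndarray, allowed: np.ndarray, n_strokes: int,
                  y0: int, y1: int, x0: int, x1: int,
                  rng: np.random.Generator) -> None:
    """Paint short anti-aliased dark-blue strokes inside a tile's WM area."""
    h, w = image.shape[:2]
    cy = rng.uniform(y0, y1, size=n_strokes)
    cx = rng.uniform(x0, x1, size=n_strokes)
    theta = rng.uniform(0, np.pi, size=n_strokes)
    half = _STROKE_LEN / 2.0
    for k in range(n_strokes):
        r0 = int(np.clip(cy[k] - half * np.sin(theta[k]), 0, h - 1))
        c0 = int(np.clip(cx[k] - half * np.cos(theta[k]), 0, w - 1))
        r1 = int(np.clip(cy[k] + half * np.sin(theta[k]), 0, h - 1))
        c1 = int(np.clip(cx[k] + half * np.cos(theta[k]), 0, w - 1))
        rr, cc, val = line_aa(r0, c0, r1, c1)
        keep = allowed[rr, cc]
        rr, cc, val = rr[keep], cc[keep], val[keep]
        image[rr, cc] = (1.0 - val[:, None]) * image[rr, cc] + val[:, None] * _DARK_BLUE_FIBER


def _scatter_nuclei(image: np.ndarray, region: np.ndarray, density_per_kpx: float,
                    rng: np.random.Generator) -> None:
    """Poisson-scattered dark nucleus dots (2x2 px) within a compartment."""
    idx = np.flatnonzero(region.ravel())
    if idx.size == 0:
        return
    n = rng.poisson(density_per_kpx * idx.size / 1000.0)
    if n == 0:
        return
    pos = rng.choice(idx, size=n)
    h, w = region.shape
    ys, xs = pos // w, pos % w
    for dy in (0, 1):
        for dx in (0, 1):
            yy = np.clip(ys + dy, 0, h - 1)
            xx = np.clip(xs + dx, 0, w - 1)
            image[yy, xx] = _NUCLEUS


def generate_slide(donor: DonorRecord, config: SimConfig,
                   tile_size: int = 256, two_pieces: bool = False) -> SyntheticSlide:
    """Render one donor's slide; deterministic under (config.seed, donor_id).

    White-matter dark-blue stroke density targets ``base_density`` for
    truly unimpaired donors; for impaired donors a ``patchiness`` fraction
    of white-matter tiles is reduced by ``effect_size``.  The ground-truth
    per-tile dark-blue fraction is measured on the rendered image *before*
    the per-slide stain gain is applied.
    """
    donor_key = int(donor.donor_id.lstrip("D")) if donor.donor_id.lstrip("D").isdigit() else 0
    rng = np.random.default_rng([config.seed, 202, donor_key])
    px = config.slide_px
    if px < 2 * tile_size:
        raise ConfigError("slide_px too small to contain both compartments as tiles")

    tissue, wm = _compartment_masks(px, config.wm_fraction, rng, two_pieces)
    gm = tissue & ~wm

    image = np.empty((px, px, 3), dtype=np.float64)
    image[:] = _BACKGROUND
    image[gm] = _GM_PINK
    # WM background carries per-pixel intensity texture (multiplicative, so
    # hue and saturation are untouched).  The spread is wide enough that the
    # light-blue band holds the background's lower intensity tail: a global
    # stain gain then moves pixels across the light band's upper gate at a
    # fractional rate comparable to the dark band's, which is what lets the
    # dark/light ratio cancel per-slide gain.  The lower tail is truncated
    # so unstroked background stays out of the dark intensity band.
    n_wm = int(wm.sum())
    texture = 1.0 + 0.25 * np.clip(rng.standard_normal(n_wm), -0.85, 2.5)
    image[wm] = _WM_LIGHT_BLUE[None, :] * texture[:, None]

    impaired = donor.true_state == "CI"
    n_rows = n_cols = px // tile_size
    mean_stroke_px = _STROKE_LEN + 1  # anti-aliased footprint, approximate
    for r in range(n_rows):
        for c in range(n_cols):
            y0, x0 = r * tile_size, c * tile_size
            tile_wm = wm[y0:y0 + tile_size, x0:x0 + tile_size]
            wm_px = int(tile_wm.sum())
            if wm_px == 0:
                continue
            density = config.base_density
            if impaired and rng.random() < config.patchiness:
                density *= (1.0 - config.effect_size)
            n_strokes = int(round(density * wm_px / mean_stroke_px))
            _draw_strokes(image, wm, n_strokes,
                          y0, y0 + tile_size, x0, x0 + tile_size, rng)

    _scatter_nuclei(image, gm, density_per_kpx=1.0, rng=rng)
    _scatter_nuclei(image, wm, density_per_kpx=0.2, rng=rng)

    pre_gain = np.clip(np.round(image), 0, 255).astype(np.uint8)
    true_density = np.zeros((n_rows, n_cols))
    for r in range(n_rows):
        for c in range(n_cols):
            tile = pre_gain[r * tile_size:(r + 1) * tile_size,
                            c * tile_size:(c + 1) * tile_size]
            true_density[r, c] = count_positive(tile, DARK_BLUE) / tile_size ** 2

    gain = float(np.clip(rng.normal(1.0, config.stain_gain_sd), 0.5, 1.5))
    final = np.clip(np.round(image * gain), 0, 255).astype(np.uint8)

    mask = np.zeros((px, px), dtype=np.uint8)
    mask[gm] = 1
    mask[wm] = 2
    return SyntheticSlide(image=final, region_mask=mask,
                          true_tile_density=true_density,
                          donor_id=donor.donor_id, gain=gain)


# -- I/O -----------------------------------------------------------------

def cohort_to_frame(records: list[DonorRecord], region: str = "hippocampus",
                    slide_dir: str = "") -> pd.DataFrame:
    """Cohort table with the canonical column set."""
    rows = []
    for rec in records:
        rows.append({
            "donor_id": rec.donor_id,
            "age": rec.age,
            "sex": rec.sex,
            "cdr": rec.cdr,
            "mmse": rec.mmse,
            "clinical_dx": rec.clinical_dx,
            "braak": rec.braak,
            "cerad": rec.cerad,
            "artag": rec.artag,
            "cvd": rec.cvd,
            "region": region,
            "slide_path": str(Path(slide_dir) / f"{rec.donor_id}.png") if slide_dir else "",
        })
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def write_cohort_csv(records: list[DonorRecord], path: str | Path,
                     region: str = "hippocampus", slide_dir: str = "") -> pd.DataFrame:
    frame = cohort_to_frame(records, region=region, slide_dir=slide_dir)
    frame.to_csv(path, index=False)
    return frame


def write_slide(slide: SyntheticSlide, image_path: str | Path,
                mask_path: str | Path | None = None,
                density_path: str | Path | None = None) -> None:
    """Persist a slide as RGB PNG, mask as single-channel PNG, densities as CSV."""
    Image.fromarray(slide.image).save(image_path)
    if mask_path is not None:
        Image.fromarray(slide.region_mask, mode="L").save(mask_path)
    if density_path is not None:
        rows, cols = slide.true_tile_density.shape
        rr, cc = np.mgrid[0:rows, 0:cols]
        pd.DataFrame({
            "donor_id": slide.donor_id,
            "tile_row": rr.ravel(),
            "tile_col": cc.ravel(),
            "true_tile_density": slide.true_tile_density.ravel(),
        }).to_csv(density_path, index=False)
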