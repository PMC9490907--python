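"""Run configuration for the LFB attention-MIL pipeline.

All tunables live in plain dataclasses so a run is reproducible from its
config alone.  :class:`RunConfig` composes the per-stage blocks and can be
round-tripped through YAML; every output artifact echoes the config it was
produced under.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "ConfigError",
    "SimConfig",
    "LabelPolicy",
    "TilingConfig",
    "MILConfig",
    "HueRangeParams",
    "StatsConfig",
    "RunConfig",
    "DARK_BLUE",
    "LIGHT_BLUE",
]


class ConfigError(ValueError):
    """Raised when a configuration value violates its contract."""


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort and slide generator.

    The generator plants a myelin-pallor effect: white-matter dark-blue
    pixel density is reduced by ``effect_size`` in truly impaired donors,
    over a ``patchiness`` fraction of the white matter.  Cognitive measures
    are derived from the true state, then corrupted at rate ``label_noise``
    and masked at rate ``missingness`` so the labels the classifier sees are
    noisy, as with real antemortem cognitive data.
    """

    n_donors: int = 120
    p_impaired: float = 0.5
    effect_size: float = 0.3
    patchiness: float = 1.0
    label_noise: float = 0.1
    missingness: float = 0.2
    age_mean: float = 85.0
    age_sd: float = 8.0
    age_ci_slope: float = 0.08
    stain_gain_sd: float = 0.05
    slide_px: int = 1024
    wm_fraction: float = 0.45
    base_density: float = 0.18
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_impaired", "patchiness", "label_noise", "missingness", "wm_fraction"):
            _check_prob(name, getattr(self, name))
        if not (0.0 <= self.effect_size < 1.0):
            raise ConfigError(f"effect_size must lie in [0, 1), got {self.effect_size!r}")
        if self.slide_px < 512:
            raise ConfigError(f"slide_px must be >= 512, got {self.slide_px!r}")
        if self.n_donors < 1:
            raise ConfigError("n_donors must be positive")
        if not (0.0 < self.base_density < 1.0):
            raise ConfigError("base_density must lie in (0, 1)")


@dataclass(frozen=True)
class LabelPolicy:
    """How CDR, clinical diagnosis and MMSE combine into a CI/NCI label.

    ``any_evidence`` (default): a donor is CI if any available measure is
    positive, NCI if at least one measure is available and all are negative,
    excluded when none is available.  ``hierarchical``: the first available
    measure in the order CDR, diagnosis, MMSE decides alone.
    """

    mode: str = "any_evidence"
    cdr_threshold: float = 0.5
    mmse_threshold: int = 24
    cdr_cap: float = 3.0

    def __post_init__(self) -> None:
        if self.mode not in ("any_evidence", "hierarchical"):
            raise ConfigError(f"unknown label policy mode {self.mode!r}")


@dataclass(frozen=True)
class TilingConfig:
    tile_size: int = 256
    min_tissue: float = 0.5
    saturation_threshold: float = 0.05
    median_disk: int = 2
    feature_dim: int = 1024

    def __post_init__(self) -> None:
        if self.tile_size < 1:
            raise ConfigError("tile_size must be positive")
        _check_prob("min_tissue", self.min_tissue)


@dataclass(frozen=True)
class MILConfig:
    """Hyperparameters of the gated attention-MIL classifier."""

    embed_dim: int = 64
    attn_dim: int = 48
    gated: bool = True
    dropout: float = 0.25
    instance_loss_weight: float = 0.3
    instance_k: int = 8
    lr: float = 2e-4
    weight_decay: float = 0.004  # per-step decoupled multiplicative shrinkage
    max_epochs: int = 150
    patience: int = 10
    early_stopping_metric: str = "loss"  # or "auc"
    n_folds: int = 10
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)

    def __post_init__(self) -> None:
        _check_prob("dropout", self.dropout)
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ConfigError("split fractions must sum to 1")
        if self.early_stopping_metric not in ("loss", "auc"):
            raise ConfigError("early_stopping_metric must be 'loss' or 'auc'")


@dataclass(frozen=True)
class HueRangeParams:
    """A positive-pixel band in HSI space.

    Membership: circular hue distance to ``hue_center`` at most
    ``hue_width / 2``, saturation at least ``saturation_min``, and intensity
    in the half-open interval ``[intensity_min, intensity_max)``.  Achromatic
    pixels (undefined hue) are never positive.
    """

    hue_center: float
    hue_width: float
    saturation_min: float
    intensity_min: float
    intensity_max: float
    name: str = "band"

    def __post_init__(self) -> None:
        if not (0.0 <= self.hue_center < 360.0):
            raise ConfigError("hue_center must lie in [0, 360)")
        if self.intensity_min >= self.intensity_max:
            raise ConfigError("intensity_min must be < intensity_max")
        _check_prob("saturation_min", self.saturation_min)


# Artifact defaults for the two blue bands.  The synthetic generator emits its
# stains from these same bands, so pixel-range recovery is testable end to end.
DARK_BLUE = HueRangeParams(240.0, 80.0, 0.15, 0.0, 120.0, name="dark_blue")
LIGHT_BLUE = HueRangeParams(240.0, 80.0, 0.15, 120.0, 220.0, name="light_blue")


@dataclass(frozen=True)
class StatsConfig:
    n_perm: int = 10_000
    n_levels: int = 3
    zero_positive_rule: str = "dark_only"  # or "either_band"

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ConfigError("n_perm must be positive")
        if self.n_levels < 2:
            raise ConfigError("n_levels must be >= 2")
        if self.zero_positive_rule not in ("dark_only", "either_band"):
            raise ConfigError("zero_positive_rule must be 'dark_only' or 'either_band'")


@dataclass(frozen=True)
class RunConfig:
    """Top-level configuration: one block per pipeline stage."""

    sim: SimConfig = field(default_factory=SimConfig)
    labels: LabelPolicy = field(default_factory=LabelPolicy)
    tiling: TilingConfig = field(default_factory=TilingConfig)
    mil: MILConfig = field(default_factory=MILConfig)
    dark_band: HueRangeParams = DARK_BLUE
    light_band: HueRangeParams = LIGHT_BLUE
    stats: StatsConfig = field(default_factory=StatsConfig)
    top_k: int = 100
    z_scope: str = "slide"  # or "cohort"
    outdir: str = "runs/demo"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.z_scope not in ("slide", "cohort"):
            raise ConfigError("z_scope must be 'slide' or 'cohort'")
        if self.top_k < 1:
            raise ConfigError("top_k must be >= 1")

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        kwargs: dict[str, Any] = {}
        blocks = {
            "sim": SimConfig,
            "labels": LabelPolicy,
            "tiling": TilingConfig,
            "mil": MILConfig,
            "dark_band": HueRangeParams,
            "light_band": HueRangeParams,
            "stats": StatsConfig,
        }
        for key, value in d.items():
            if key in blocks and isinstance(value, dict):
                if key == "mil" and "fractions" in value:
                    value = {**value, "fractions": tuple(value["fractions"])}
                kwargs[key] = blocks[key](**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
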