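"""Validated pipeline configuration (TOML-loadable).

Unknown keys are rejected by name; every numeric field is range-checked
on load so a bad config fails before any stage runs.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SegmentationConfig(_Strict):
    threshold: float | str = "otsu"
    min_nucleus_area_um2: float = Field(20.0, ge=0)
    blur_sigma: float = Field(0.0, ge=0)
    exclude_border: bool = False


class DropletStageConfig(_Strict):
    """Dish groups with their mean contact angles and replicate SDs (degrees)."""

    angles_deg: dict[str, float] = Field(
        default_factory=lambda: {"FPI": 93.0, "Matsunami": 71.0, "plastic": 66.0}
    )
    jitter_sd_deg: dict[str, float] = Field(
        default_factory=lambda: {"FPI": 2.0, "Matsunami": 4.0, "plastic": 3.0}
    )
    n_per_group: int = Field(10, ge=2)
    base_radius_px: float = Field(100.0, ge=10)


class TimecourseStageConfig(_Strict):
    """R_multi trajectories (% multinucleated vs hours) per culture condition.

    Default anchors: the treatment condition (less hydrophilic dish +
    ROCK inhibitor) climbs to 88% at 48 h; every control stays at or
    below 5%.  Intermediate values are illustrative, not measured.
    """

    n_cells: int = Field(100, ge=10)
    trajectories: dict[str, dict[float, float]] = Field(
        default_factory=lambda: {
            "FPI+Y27632": {12.0: 20.0, 24.0: 55.0, 48.0: 88.0},
            "FPI": {12.0: 1.0, 24.0: 2.0, 48.0: 4.0},
            "Matsunami+Y27632": {12.0: 1.0, 24.0: 3.0, 48.0: 5.0},
            "Matsunami": {12.0: 0.0, 24.0: 1.0, 48.0: 2.0},
        }
    )


class MorphometryStageConfig(_Strict):
    """Generator settings for the mono vs multi morphometry comparison.

    Multinucleated cells are drawn larger (a cell that skipped
    cytokinesis keeps roughly the volume of two) with more elongated
    nuclei, while their per-nucleus Wilson ratio is smaller — the
    directions the morphometric contrast is expected to show.
    """

    n_cells_per_group: int = Field(100, ge=4)
    ratio_mode: str = "per_nucleus"
    mono_cell_area_um2: tuple[float, float] = (1400.0, 350.0)
    multi_cell_area_um2: tuple[float, float] = (2400.0, 500.0)
    mono_nucleus_ecc: tuple[float, float] = (0.0, 0.5)
    multi_nucleus_ecc: tuple[float, float] = (0.45, 0.8)
    mono_ratio_pct: tuple[float, float] = (5.9, 2.1)
    per_nucleus_ratio_pct: tuple[float, float] = (2.4, 0.6)
    summed_ratio_pct: tuple[float, float] = (5.0, 1.3)


class PipelineConfig(_Strict):
    pixel_size_um: float = Field(0.664, gt=0)
    seed: int = 0
    circularity_convention: str = "roundness"
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    droplets: DropletStageConfig = Field(default_factory=DropletStageConfig)
    timecourse: TimecourseStageConfig = Field(default_factory=TimecourseStageConfig)
    morphometry: MorphometryStageConfig = Field(default_factory=MorphometryStageConfig)


def load_config(path: Path | str | None = None) -> PipelineConfig:
    """Load a TOML config file; omitted keys take defaults, unknown keys
    raise a validation error naming the key."""
    if path is None:
        return PipelineConfig()
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return PipelineConfig(**data)
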