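"""Run configuration: one serializable object drives a whole run.

A :class:`RunConfig` captures everything needed to regenerate a run —
layout, gradient, imaging, schedule and analysis options — and round-trips
through YAML; each run directory receives a copy of the exact config used.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synthetic import (
    GradientConfig,
    LayoutConfig,
    RenderConfig,
    default_morphotypes,
)

__all__ = ["RunConfig", "load_config", "save_config"]

_DEFAULT_SPECIES = [
    "rosette", "caulescent", "bush-spurge", "bush-herb",
    "grass-temperate", "grass-erect", "grass-c4",
]


@dataclass
class RunConfig:
    """All knobs of a synthetic run and its analysis."""

    seed: int = 0
    # layout
    species: list[str] = field(default_factory=lambda: list(_DEFAULT_SPECIES))
    rows_per_species: int = 3
    rosette_reference: str = "rosette"  # gets one extra row of replication
    rosette_rows: int = 4
    columns_per_room: int = 12
    rows_per_room: int = 10
    # gradient
    min_ratio: float = 0.1
    max_ratio: float = 10.0
    ratio_noise_sd: float = 0.05
    # schedule
    treatment_days: int = 31
    sessions_per_week: int = 2
    treatment_end: float = 31.0
    # imaging / rendering
    image_width: int = 200
    image_height: int = 200
    mm_per_px: float = 2.0
    chart: bool = False
    min_area_px: int = 25
    # analysis
    effect_baseline: str = "min"
    fdr: bool = False
    pca_day_min: float = 21.0
    pca_day_max: float = 29.0
    exclude_side_for: list[str] = field(default_factory=lambda: ["rosette"])

    def layout_config(self) -> LayoutConfig:
        rows = {
            s: (self.rosette_rows if s == self.rosette_reference
                else self.rows_per_species)
            for s in self.species
        }
        return LayoutConfig(
            species_rows=rows,
            columns_per_room=self.columns_per_room,
            rows_per_room=self.rows_per_room,
        )

    def gradient_config(self) -> GradientConfig:
        return GradientConfig(
            min_ratio=self.min_ratio, max_ratio=self.max_ratio,
            ratio_noise_sd=self.ratio_noise_sd,
        )

    def render_config(self) -> RenderConfig:
        return RenderConfig(
            width_px=self.image_width, height_px=self.image_height,
            mm_per_px=self.mm_per_px, chart=self.chart,
        )

    def morphotypes(self):
        pool = default_morphotypes()
        missing = [s for s in self.species if s not in pool]
        if missing:
            raise ValueError(f"unknown morphotype(s): {missing}")
        return {s: pool[s] for s in self.species}

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)
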