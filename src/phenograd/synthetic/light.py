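"""Red:blue gradient light map over the layout columns.

Five LED clusters span the columns; each cluster is set to a red:blue
ratio, log-spaced between the gradient endpoints, and the ratio measured at
a pot interpolates linearly in ln(ratio) between cluster centers (so
ln(ratio) is piecewise-affine and monotone across columns before
measurement noise). Total irradiance (PPFD) is held inside a fixed band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .layout import ExperimentLayout

__all__ = ["GradientConfig", "LightPoint", "build_light_map", "light_frame"]


@dataclass
class GradientConfig:
    """Gradient endpoints, cluster count, PPFD band and measurement noise.

    Ratios are dimensionless red:blue photon-flux ratios; the default
    0.1–10 span covers two decades symmetric around 1. ``ratio_noise_sd``
    is the SD of the per-pot noise on ln(ratio) (measurement + local
    non-uniformity); PPFD in µmol m⁻² s⁻¹.
    """

    min_ratio: float = 0.1
    max_ratio: float = 10.0
    n_clusters: int = 5
    ratio_noise_sd: float = 0.05
    ppfd_center: float = 125.0
    ppfd_band: tuple[float, float] = (100.0, 150.0)
    ppfd_noise_sd: float = 8.0

    def __post_init__(self) -> None:
        if self.min_ratio <= 0:
            raise ValueError("min_ratio must be positive")
        if self.max_ratio < self.min_ratio:
            raise ValueError("max_ratio must be >= min_ratio")


@dataclass(frozen=True)
class LightPoint:
    """Measured light at one pot position."""

    pot_uid: str
    red_pfd: float
    blue_pfd: float
    ratio: float
    ppfd: float


def column_log_ratios(config: GradientConfig, n_columns: int) -> np.ndarray:
    """Noise-free ln(ratio) per column: cluster set-points, interpolated."""
    centers = np.linspace(0, n_columns - 1, config.n_clusters)
    setpoints = np.linspace(
        math.log(config.min_ratio), math.log(config.max_ratio), config.n_clusters
    )
    return np.interp(np.arange(n_columns), centers, setpoints)


def build_light_map(
    layout: ExperimentLayout, config: GradientConfig, seed: int
) -> list[LightPoint]:
    """Measured red:blue ratio and PPFD at every pot. Deterministic per seed.

    Red and blue photon flux densities are back-computed from the ratio
    assuming the red+blue channels carry ~80% of total PPFD, so
    ``ratio == red_pfd / blue_pfd`` holds exactly.
    """
    rng = np.random.default_rng(seed)
    col_ln = column_log_ratios(config, layout.config.columns_per_room)
    points: list[LightPoint] = []
    for pot in layout.pots:
        ln_ratio = col_ln[pot.column] + rng.normal(0.0, config.ratio_noise_sd)
        ratio = math.exp(ln_ratio)
        lo, hi = config.ppfd_band
        ppfd = float(np.clip(
            rng.normal(config.ppfd_center, config.ppfd_noise_sd), lo, hi))
        rb = 0.8 * ppfd
        blue = rb / (1.0 + ratio)
        points.append(LightPoint(pot.uid, rb - blue, blue, ratio, ppfd))
    return points


def light_frame(layout: ExperimentLayout, points: list[LightPoint]) -> pd.DataFrame:
    """Layout + light map as one tidy table keyed by pot_uid."""
    by_uid = {p.uid: p for p in layout.pots}
    rows = []
    for lp in points:
        pot = by_uid[lp.pot_uid]
        rows.append({
            "pot_uid": lp.pot_uid, "species": pot.species, "room": pot.room,
            "row": pot.row, "column": pot.column, "replicate": pot.replicate,
            "ratio": lp.ratio, "red_pfd": lp.red_pfd, "blue_pfd": lp.blue_pfd,
            "ppfd": lp.ppfd,
        })
    return pd.DataFrame(rows)
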