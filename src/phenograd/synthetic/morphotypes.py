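"""Parametric plant morphotypes with programmed light-quality responses.

A morphotype stands in for a species: a growth habit (rosette, caulescent,
bush or grass), baseline descriptor values, and per-descriptor *effect
curves* describing how strongly the descriptor responds to the red:blue
gradient as a function of time. The response of every affected descriptor
is linear in ln(red:blue ratio):

    value(day, r) = baseline(day) * (1 + E(day)/100 * u(r)),
    u(r) = (ln r - ln r_min) / (ln r_max - ln r_min),

so the programmed percentage difference across the gradient span
[r_min, r_max] at a given day is exactly ``E(day)`` — the quantity the
gradient-regression "effect size" estimates. ``E(day)`` follows a
gamma-shaped rise–peak–decay curve so transient responses (and acclimation
after a peak) can be emulated; decay 0 degenerates to a ramp-and-hold,
i.e. a sustained effect.

Noise model: multiplicative log-normal (mean-preserving) on dimensions,
additive Gaussian on color channels clipped to [0, 255], additive Gaussian
on shape factors clipped to (0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["EffectCurve", "Morphotype", "make_morphotype", "default_morphotypes"]

# growth-scaling exponent per dimension descriptor: lengths grow ~g(t),
# areas ~g(t)^2, the volume proxy ~g(t)^3; shape and color stay flat.
_GROWTH_EXPONENT = {
    "side_HeightMax": 1, "side_WidthMax": 1, "top_MeanFeret": 1,
    "side_AreaMean": 2, "top_Area": 2, "Voxel": 3,
}


@dataclass(frozen=True)
class EffectCurve:
    """Time course of a descriptor's programmed gradient effect (%).

    ``peak_percent`` is the percentage difference across the full gradient
    span at the peak of the response. The curve is 0 before ``onset_day``,
    rises to the peak at ``peak_day`` and decays at rate ``decay`` (shape
    parameter of a gamma-like pulse); ``decay=0`` holds the peak value
    indefinitely (sustained effect).
    """

    peak_percent: float
    onset_day: float = 0.0
    peak_day: float = 14.0
    decay: float = 1.0

    def percent(self, day: float) -> float:
        if day <= self.onset_day or self.peak_percent == 0.0:
            return 0.0
        u = (day - self.onset_day) / (self.peak_day - self.onset_day)
        if self.decay == 0.0:
            return self.peak_percent * min(u, 1.0)
        a = self.decay
        return self.peak_percent * float(u ** a * math.exp(a * (1.0 - u)))


@dataclass
class Morphotype:
    """A species stand-in: habit, baseline descriptors, gradient effects."""

    name: str
    habit: str  # rosette | caulescent | bush | grass
    baselines: dict[str, float]
    effects: dict[str, EffectCurve] = field(default_factory=dict)
    n_plants: int = 1  # plants per pot (bush species are sown in groups)
    leaf_angle_deg: float = 45.0  # grass blade angle from vertical
    n_leaves: int = 8
    growth_floor: float = 0.35  # relative size at treatment start
    growth_tau: float = 12.0  # days to ~63% of remaining growth
    noise_cv: float = 0.10  # CV of dimension noise (log-normal)
    color_noise_sd: float = 3.0
    shape_noise_sd: float = 0.02

    def growth_scale(self, day: float) -> float:
        g = self.growth_floor + (1.0 - self.growth_floor) * (
            1.0 - math.exp(-day / self.growth_tau)
        )
        return g

    def descriptor_mean(
        self, name: str, day: float, ln_ratio: float,
        ln_min: float, ln_max: float,
    ) -> float:
        """Noise-free value of one descriptor at (day, position)."""
        base = self.baselines[name]
        base *= self.growth_scale(day) ** _GROWTH_EXPONENT.get(name, 0)
        curve = self.effects.get(name)
        if curve is not None and ln_max > ln_min:
            u = (ln_ratio - ln_min) / (ln_max - ln_min)
            base *= 1.0 + curve.percent(day) / 100.0 * u
        return base


def _habit_shape_baselines(habit: str) -> dict[str, float]:
    # typical silhouette factors per habit; top views are rounder than side
    presets = {
        "rosette": dict(side=(0.55, 0.75, 0.80, 0.45, 0.70),
                        top=(0.85, 0.80, 0.75, 0.45, 0.90)),
        "caulescent": dict(side=(0.45, 0.55, 0.60, 0.20, 0.60),
                           top=(0.75, 0.65, 0.60, 0.25, 0.80)),
        "bush": dict(side=(0.60, 0.65, 0.55, 0.25, 0.75),
                     top=(0.80, 0.70, 0.55, 0.30, 0.85)),
        "grass": dict(side=(0.35, 0.40, 0.45, 0.10, 0.50),
                      top=(0.55, 0.45, 0.40, 0.12, 0.65)),
    }
    keys = ("Roundness", "Solidity", "Convexity", "Circularity", "Compactness")
    sel = presets[habit]
    out: dict[str, float] = {}
    for prefix in ("side", "top"):
        for k, v in zip(keys, sel[prefix]):
            out[f"{prefix}_{k}"] = v
    return out


def _color_baselines(rgb: tuple[float, float, float], area_px: float) -> dict[str, float]:
    import matplotlib.colors as mcolors

    r, g, b = rgb
    h, s, v = mcolors.rgb_to_hsv(np.array(rgb) / 255.0)
    out: dict[str, float] = {}
    for prefix in ("side", "top"):
        out.update({
            f"{prefix}_RedMean": r, f"{prefix}_GreenMean": g,
            f"{prefix}_BlueMean": b,
            f"{prefix}_HueMean": h * 255.0, f"{prefix}_HueCv": 6.0,
            f"{prefix}_SaturationMean": s * 255.0,
            f"{prefix}_BrightnessMean": v * 255.0,
            f"{prefix}_Density": area_px * (r + g + b) / 3.0,
        })
    return out


def make_morphotype(
    name: str,
    habit: str,
    *,
    height_mm: float,
    spread_mm: float,
    color: tuple[float, float, float],
    cover: float = 0.35,
    n_plants: int = 1,
    leaf_angle_deg: float = 45.0,
    n_leaves: int = 8,
    effects: dict[str, EffectCurve] | None = None,
    calibration_mm_per_px: float = 2.0,
    **kwargs,
) -> Morphotype:
    """Build a morphotype from a few size/habit parameters.

    ``height_mm``/``spread_mm`` are asymptotic shoot height and lateral
    spread; ``cover`` the fraction of the bounding box the silhouette fills;
    ``color`` the mean plant RGB. Derived baselines (projected areas, volume
    proxy, integrated density) are filled in consistently.
    """
    side_area = cover * height_mm * spread_mm
    top_area = cover * math.pi / 4.0 * spread_mm ** 2
    baselines: dict[str, float] = {
        "side_HeightMax": height_mm,
        "side_WidthMax": spread_mm,
        "side_AreaMean": side_area,
        "top_Area": top_area,
        "top_MeanFeret": 0.85 * spread_mm,
        "Voxel": side_area * math.sqrt(top_area),
    }
    baselines.update(_habit_shape_baselines(habit))
    baselines.update(_color_baselines(color, top_area / calibration_mm_per_px ** 2))
    return Morphotype(
        name=name, habit=habit, baselines=baselines, effects=effects or {},
        n_plants=n_plants, leaf_angle_deg=leaf_angle_deg, n_leaves=n_leaves,
        **kwargs,
    )


def default_morphotypes() -> dict[str, Morphotype]:
    """Seven morphotypes spanning the habits and responses of a multi-species
    gradient screen.

    The set mixes a compact rosette reference (top view only is
    informative), a tall caulescent dicot with a *transient* elongation
    response peaking two weeks into the treatment, two multi-plant bushes
    (one unresponsive during the gradient), and three grasses with
    sustained, slowly developing dimension/shape responses — one of them
    with a color response of opposite sign. Effects act on height, shape
    and color descriptors, always linearly in ln(red:blue).
    """
    m: dict[str, Morphotype] = {}
    m["rosette"] = make_morphotype(
        "rosette", "rosette", height_mm=40, spread_mm=95,
        color=(70, 120, 45), cover=0.45, n_leaves=11,
        effects={
            "top_Circularity": EffectCurve(-20, onset_day=3, peak_day=18, decay=0.6),
            "top_GreenMean": EffectCurve(8, onset_day=3, peak_day=20, decay=0),
        },
    )
    m["caulescent"] = make_morphotype(
        "caulescent", "caulescent", height_mm=230, spread_mm=150,
        color=(60, 130, 60), cover=0.30, n_leaves=7,
        effects={
            # transient: strongest ~2 weeks in, fading afterwards
            "side_HeightMax": EffectCurve(40, onset_day=2, peak_day=14, decay=1.5),
            "Voxel": EffectCurve(60, onset_day=2, peak_day=14, decay=1.5),
            "side_Circularity": EffectCurve(-15, onset_day=2, peak_day=14, decay=1.5),
            "top_GreenMean": EffectCurve(10, onset_day=2, peak_day=14, decay=1.0),
        },
    )
    m["bush-spurge"] = make_morphotype(
        "bush-spurge", "bush", height_mm=130, spread_mm=135,
        color=(72, 128, 58), cover=0.40, n_plants=6, n_leaves=18,
        effects={
            "side_HeightMax": EffectCurve(20, onset_day=4, peak_day=24, decay=0),
            "top_Area": EffectCurve(25, onset_day=4, peak_day=24, decay=0),
        },
    )
    m["bush-herb"] = make_morphotype(
        # no significant response while the gradient is on
        "bush-herb", "bush", height_mm=170, spread_mm=150,
        color=(55, 135, 62), cover=0.35, n_plants=4, n_leaves=12,
        effects={},
    )
    m["grass-temperate"] = make_morphotype(
        "grass-temperate", "grass", height_mm=190, spread_mm=130,
        color=(68, 125, 52), cover=0.18, n_leaves=9, leaf_angle_deg=50,
        effects={
            "side_HeightMax": EffectCurve(35, onset_day=4, peak_day=26, decay=0),
            "side_AreaMean": EffectCurve(50, onset_day=4, peak_day=26, decay=0),
            "top_Area": EffectCurve(40, onset_day=4, peak_day=26, decay=0),
            "side_WidthMax": EffectCurve(25, onset_day=4, peak_day=26, decay=0),
        },
    )
    m["grass-erect"] = make_morphotype(
        "grass-erect", "grass", height_mm=260, spread_mm=105,
        color=(62, 132, 58), cover=0.15, n_leaves=7, leaf_angle_deg=30,
        effects={
            "side_Roundness": EffectCurve(-18, onset_day=4, peak_day=22, decay=0.4),
            "side_Solidity": EffectCurve(15, onset_day=4, peak_day=22, decay=0.4),
            "top_Roundness": EffectCurve(-12, onset_day=4, peak_day=22, decay=0.4),
            "top_GreenMean": EffectCurve(7, onset_day=4, peak_day=22, decay=0),
        },
    )
    m["grass-c4"] = make_morphotype(
        "grass-c4", "grass", height_mm=220, spread_mm=140,
        color=(75, 130, 48), cover=0.20, n_leaves=11, leaf_angle_deg=55,
        effects={
            # color response of opposite sign to the other species
            "top_GreenMean": EffectCurve(-8, onset_day=4, peak_day=20, decay=0),
            "top_BlueMean": EffectCurve(10, onset_day=4, peak_day=20, decay=0),
        },
    )
    return m
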