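"""Procedural 2.5-D rendering of plant silhouettes.

A plant is modelled as a stem/blade skeleton plus leaves at fixed 3-D
azimuths; the six side views are parallel projections of the same plant
rotated in 30° steps over 180° (so a leaf's horizontal reach scales with
cos(azimuth + view angle)), and the top view is its vertical projection.
Side views are drawn dark-on-light (diffusive back-lit white background),
the top view light-on-dark (black cloth background). Rendering is not
photorealistic — it is built to drive the full descriptor set (dimensions,
shape factors, color statistics) with known ground truth: the returned
masks mark exactly the generated plant pixels, and the drawn stem height
tracks the morphotype's programmed height to within rasterization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage import draw as skdraw

from ..imaging import ImageRecord, SIDE, TOP
from .light import LightPoint
from .morphotypes import Morphotype

__all__ = ["RenderConfig", "RenderError", "SyntheticScene", "render_scene"]


class RenderError(RuntimeError):
    """The plant does not fit in the frame at the current calibration."""


@dataclass
class RenderConfig:
    """Frame geometry, calibration and backgrounds."""

    width_px: int = 200
    height_px: int = 200
    mm_per_px: float = 2.0
    side_background: int = 248
    top_background: int = 12
    pixel_noise_sd: float = 2.0
    margin_px: int = 8
    chart: bool = False
    chart_bbox: tuple[int, int, int, int] = (4, 4, 18, 18)  # r0, c0, r1, c1
    chart_rgb: tuple[int, int, int] = (200, 200, 200)
    chart_size_mm: float = 28.0  # == (r1-r0) px * default 2 mm/px


@dataclass
class SyntheticScene:
    """6 side + 1 top frames with exact masks and generator ground truth."""

    records: list[ImageRecord]
    true_masks: dict[tuple[str, int], np.ndarray]
    true_color: tuple[float, float, float]
    targets: dict[str, float]
    pot_uid: str
    day: int

    def record(self, view: str, frame: int = 0) -> ImageRecord:
        for r in self.records:
            if r.view == view and r.frame_index == frame:
                return r
        raise KeyError((view, frame))


def _leaf_geometry(m: Morphotype, h_px: float, half_spread: float,
                   rng: np.random.Generator):
    """Per-leaf (azimuth deg, attach height, radial length, thickness)."""
    leaves = []
    n = m.n_leaves
    phase = rng.uniform(0, 360)
    for i in range(n):
        az = phase + i * 137.508
        if m.habit == "rosette":
            za = h_px * rng.uniform(0.05, 0.35)
            length = half_spread * rng.uniform(0.6, 1.0)
        elif m.habit == "caulescent":
            f = 0.25 + 0.65 * i / max(n - 1, 1)
            za = h_px * f
            length = half_spread * (1.0 - 0.55 * f) * rng.uniform(0.8, 1.0)
        else:  # bush sub-plant leaves
            za = h_px * rng.uniform(0.2, 0.9)
            length = half_spread * rng.uniform(0.5, 0.9)
        thick = max(2.0, 0.16 * length)
        leaves.append((az, za, length, thick))
    return leaves


def _paint(mask: np.ndarray, rr: np.ndarray, cc: np.ndarray) -> None:
    mask[rr, cc] = True


def _side_mask(m: Morphotype, h_px: float, half_spread: float,
               theta_deg: float, shape: tuple[int, int],
               base: tuple[int, int], plants, rng) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    y0, cx = base
    th = math.radians(theta_deg)
    for px_off_az, px_off_r, scale, leaves, blades in plants:
        ox = cx + px_off_r * math.cos(math.radians(px_off_az) + th)
        hp = h_px * scale
        if m.habit == "grass":
            for az, beta, lz, width in blades:
                reach = lz * math.tan(math.radians(beta))
                tipx = ox + reach * math.cos(math.radians(az) + th)
                rr, cc = skdraw.polygon(
                    *_strip(y0, ox, y0 - lz, tipx, width), shape=shape)
                _paint(mask, rr, cc)
        else:
            if m.habit != "rosette":
                rr, cc = skdraw.polygon(
                    *_strip(y0, ox, y0 - hp, ox, 2.5), shape=shape)
                _paint(mask, rr, cc)
            for az, za, length, thick in leaves:
                proj = math.cos(math.radians(az) + th)
                lx = ox + 0.55 * length * proj
                semi_x = max(1.5, 0.45 * abs(length * proj))
                semi_y = thick if m.habit != "rosette" else max(
                    thick, 0.45 * (h_px * scale - za))
                rr, cc = skdraw.ellipse(
                    y0 - za, lx, semi_y, semi_x, shape=shape)
                _paint(mask, rr, cc)
            if m.habit == "rosette":
                # central crown reaching the nominal plant height
                rr, cc = skdraw.ellipse(
                    y0 - hp / 2.0, ox, hp / 2.0, max(2.0, 0.12 * half_spread),
                    shape=shape)
                _paint(mask, rr, cc)
    mask[int(y0) + 1:, :] = False  # nothing below the pot surface
    return mask


def _top_mask(m: Morphotype, half_spread: float, shape: tuple[int, int],
              center: tuple[float, float], plants) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    cy, cx = center
    for px_off_az, px_off_r, scale, leaves, blades in plants:
        oy = cy + px_off_r * math.sin(math.radians(px_off_az))
        ox = cx + px_off_r * math.cos(math.radians(px_off_az))
        if m.habit == "grass":
            for az, beta, lz, width in blades:
                reach = lz * math.tan(math.radians(beta))
                ty = oy + reach * math.sin(math.radians(az))
                tx = ox + reach * math.cos(math.radians(az))
                rr, cc = skdraw.polygon(*_strip(oy, ox, ty, tx, width),
                                        shape=shape)
                _paint(mask, rr, cc)
            rr, cc = skdraw.disk((oy, ox), 2.5, shape=shape)
            _paint(mask, rr, cc)
        else:
            for az, za, length, thick in leaves:
                a = math.radians(az)
                ly = oy + 0.55 * length * math.sin(a)
                lx = ox + 0.55 * length * math.cos(a)
                rr, cc = skdraw.ellipse(
                    ly, lx, thick * 1.2, max(2.0, 0.45 * length),
                    rotation=-a, shape=shape)
                _paint(mask, rr, cc)
            rr, cc = skdraw.disk((oy, ox), max(2.0, 0.08 * half_spread),
                                 shape=shape)
            _paint(mask, rr, cc)
    return mask


def _strip(y1: float, x1: float, y2: float, x2: float, width: float):
    """Quad polygon vertices for a thick line segment."""
    dy, dx = y2 - y1, x2 - x1
    n = math.hypot(dy, dx) or 1.0
    uy, ux = -dx / n * width / 2.0, dy / n * width / 2.0
    return (np.array([y1 + uy, y2 + uy, y2 - uy, y1 - uy]),
            np.array([x1 + ux, x2 + ux, x2 - ux, x1 - ux]))


def render_scene(
    morphotype: Morphotype,
    light: LightPoint,
    day: int,
    seed: int,
    config: RenderConfig | None = None,
    gradient_span: tuple[float, float] = (0.1, 10.0),
) -> SyntheticScene:
    """Render the 6 side + 1 top frames of one pot on one day.

    The drawn plant's height, spread and mean color follow the morphotype's
    programmed means at (day, ln ratio) with the morphotype's noise applied
    once per scene. Raises :class:`RenderError` rather than silently
    clipping a plant that exceeds the frame.
    """
    if day < 0:
        raise ValueError("day must be >= 0")
    cfg = config or RenderConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF]))
    ln_min, ln_max = math.log(gradient_span[0]), math.log(gradient_span[1])
    lnr = math.log(light.ratio)

    def trait(name: str) -> float:
        return morphotype.descriptor_mean(name, day, lnr, ln_min, ln_max)

    cv = morphotype.noise_cv
    sigma = math.sqrt(math.log1p(cv * cv))
    dim_noise = math.exp(rng.normal(-sigma * sigma / 2.0, sigma))
    height_mm = trait("side_HeightMax") * dim_noise
    spread_mm = trait("side_WidthMax") * math.exp(
        rng.normal(-sigma * sigma / 2.0, sigma))
    color = np.array([
        trait("top_RedMean"), trait("top_GreenMean"), trait("top_BlueMean")])
    color = np.clip(color + rng.normal(0, morphotype.color_noise_sd, 3), 0, 255)

    h_px = height_mm / cfg.mm_per_px
    half_spread = spread_mm / cfg.mm_per_px / 2.0
    shape = (cfg.height_px, cfg.width_px)
    usable_h = cfg.height_px - 2 * cfg.margin_px
    usable_w = cfg.width_px - 2 * cfg.margin_px
    if h_px > usable_h or 2 * half_spread > usable_w:
        raise RenderError(
            f"plant ({height_mm:.0f} x {spread_mm:.0f} mm) exceeds the "
            f"{usable_h * cfg.mm_per_px:.0f} x {usable_w * cfg.mm_per_px:.0f} mm "
            "usable frame; enlarge the frame or coarsen mm_per_px"
        )

    # sub-plants: single specimen at the pot center, or a small group
    plants = []
    for j in range(morphotype.n_plants):
        if morphotype.n_plants == 1:
            off_az, off_r, scale = 0.0, 0.0, 1.0
        else:
            off_az = rng.uniform(0, 360)
            off_r = rng.uniform(0.15, 0.55) * half_spread
            scale = 1.0 if j == 0 else rng.uniform(0.6, 0.95)
        sub_spread = half_spread - off_r
        leaves = _leaf_geometry(morphotype, h_px * scale, sub_spread, rng)
        blades = []
        if morphotype.habit == "grass":
            nb = morphotype.n_leaves
            phase = rng.uniform(0, 360)
            for i in range(nb):
                az = phase + i * 137.508
                beta = morphotype.leaf_angle_deg * (
                    0.0 if i == 0 else rng.uniform(0.35, 1.0))
                lz = h_px * scale * (1.0 if i == 0 else rng.uniform(0.5, 0.95))
                # cap the horizontal reach at the spread budget
                reach = lz * math.tan(math.radians(beta))
                if reach > sub_spread:
                    beta = math.degrees(math.atan2(sub_spread, lz))
                blades.append((az, beta, lz, max(2.0, 0.02 * h_px)))
        plants.append((off_az, off_r, scale, leaves, blades))

    base = (cfg.height_px - cfg.margin_px - 1, cfg.width_px / 2.0)
    center = ((cfg.height_px - 1) / 2.0, (cfg.width_px - 1) / 2.0)
    records: list[ImageRecord] = []
    true_masks: dict[tuple[str, int], np.ndarray] = {}

    def compose(mask: np.ndarray, background: int, view: str, k: int):
        img = np.full(shape + (3,), float(background))
        img += rng.normal(0, 1.0, img.shape)
        pix = color[None, :] + rng.normal(
            0, cfg.pixel_noise_sd, (int(mask.sum()), 3))
        img[mask] = pix
        if cfg.chart:
            r0, c0, r1, c1 = cfg.chart_bbox
            img[r0:r1, c0:c1] = np.array(cfg.chart_rgb, float) + rng.normal(
                0, 1.0, (r1 - r0, c1 - c0, 3))
        rec = ImageRecord(
            pixels=np.clip(img, 0, 255).astype(np.uint8),
            pot_uid=light.pot_uid, view=view, frame_index=k, day=day,
            calibration=cfg.mm_per_px,
        )
        records.append(rec)
        true_masks[(view, k)] = mask

    for k in range(6):
        mask = _side_mask(morphotype, h_px, half_spread, 30.0 * k,
                          shape, base, plants, rng)
        compose(mask, cfg.side_background, SIDE, k)
    mask_top = _top_mask(morphotype, half_spread, shape, center, plants)
    compose(mask_top, cfg.top_background, TOP, 0)

    targets = {
        "height_mm": height_mm, "spread_mm": spread_mm,
        "red": float(color[0]), "green": float(color[1]),
        "blue": float(color[2]),
    }
    return SyntheticScene(
        records=records, true_masks=true_masks,
        true_color=tuple(color), targets=targets,
        pot_uid=light.pot_uid, day=day,
    )
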