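"""Whole-experiment generation: images on disk or descriptor tables in memory.

Two paths share the same morphotype parameterization:

* :func:`generate_experiment` renders and writes every frame as PNG plus a
  metadata table and a mask-derived ground-truth descriptor table — the
  input the full image pipeline is validated against;
* :func:`simulate_descriptor_table` skips rendering and draws descriptor
  values directly from the morphotype means and noise model — the fast path
  for statistical validation (effect-size recovery, null calibration, PCA),
  where thousands of pot×day records are needed.
"""

from __future__ import annotations

import math
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .. import descriptors as desc
from ..imaging import PlantMask, SIDE, TOP
from .layout import ExperimentLayout
from .light import GradientConfig, LightPoint, light_frame
from .morphotypes import Morphotype
from .render import RenderConfig, SyntheticScene, render_scene

__all__ = [
    "default_schedule",
    "generate_experiment",
    "simulate_descriptor_table",
    "scene_ground_truth",
]


def default_schedule(treatment_days: int = 31, sessions_per_week: int = 2,
                     start_day: int = 0) -> list[int]:
    """Imaging days at ``sessions_per_week`` over the treatment window."""
    if sessions_per_week < 1:
        raise ValueError("sessions_per_week must be >= 1")
    offsets = np.round(np.arange(sessions_per_week) * 7.0 / sessions_per_week)
    days = sorted({
        int(start_day + 7 * week + off)
        for week in range(treatment_days // 7 + 2)
        for off in offsets
    })
    return [d for d in days if d <= start_day + treatment_days]


def _pot_seed(seed: int, pot_uid: str, day: int) -> int:
    mix = np.random.SeedSequence(
        [seed & 0x7FFFFFFF, zlib.crc32(pot_uid.encode()), day]
    )
    return int(mix.generate_state(1)[0] & 0x7FFFFFFF)


def scene_ground_truth(scene: SyntheticScene) -> dict[str, float]:
    """Descriptor ground truth of a rendered scene, from its exact masks."""
    cal = scene.records[0].calibration or 1.0
    side = []
    top = None
    for rec in scene.records:
        mask = PlantMask(
            pixels=scene.true_masks[(rec.view, rec.frame_index)],
            calibration=cal, view=rec.view,
            pot_uid=scene.pot_uid, day=scene.day,
        )
        vm = desc.measure_view(rec, mask)
        if rec.view == SIDE:
            side.append(vm)
        else:
            top = vm
    dv = desc.aggregate_views(side, top, pot_uid=scene.pot_uid, day=scene.day)
    return dv.values


def generate_experiment(
    layout: ExperimentLayout,
    light_map: list[LightPoint],
    morphotypes: dict[str, Morphotype],
    schedule: list[int],
    seed: int,
    out_dir: str | Path,
    render_config: RenderConfig | None = None,
    gradient_config: GradientConfig | None = None,
) -> dict[str, Path]:
    """Render one scene per pot per scheduled day and write the run to disk.

    Layout: ``images/<potUID>_<day>_<view>_<frame>.png`` (":" in pot UIDs
    becomes "-" in file names), ``metadata.csv`` (pot_uid, species, room,
    row, column, ratio, ppfd, day), ``ground_truth.csv`` (mask-derived
    descriptors, ``true_`` prefix). I/O and rendering failures are re-raised
    with the offending pot UID in the message.
    """
    if not schedule:
        raise ValueError("imaging schedule is empty")
    if sorted(schedule) != list(schedule):
        raise ValueError("imaging schedule must be sorted")
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    cfg = render_config or RenderConfig()
    gcfg = gradient_config or GradientConfig()
    span = (gcfg.min_ratio, gcfg.max_ratio)
    base = light_frame(layout, light_map)
    by_uid = {lp.pot_uid: lp for lp in light_map}
    meta_rows, truth_rows = [], []
    for pot in layout.pots:
        lp = by_uid[pot.uid]
        morph = morphotypes[pot.species]
        for day in schedule:
            try:
                scene = render_scene(
                    morph, lp, day, _pot_seed(seed, pot.uid, day),
                    config=cfg, gradient_span=span,
                )
                safe_uid = pot.uid.replace(":", "-")
                for rec in scene.records:
                    name = f"{safe_uid}_{day}_{rec.view}_{rec.frame_index}.png"
                    Image.fromarray(rec.pixels).save(out / "images" / name)
                meta_rows.append({
                    "pot_uid": pot.uid, "species": pot.species,
                    "room": pot.room, "row": pot.row, "column": pot.column,
                    "ratio": lp.ratio, "ppfd": lp.ppfd, "day": day,
                })
                truth = {"pot_uid": pot.uid, "species": pot.species,
                         "day": day, "ratio": lp.ratio}
                truth.update({
                    f"true_{k}": v for k, v in scene_ground_truth(scene).items()
                })
                truth_rows.append(truth)
            except Exception as exc:
                raise RuntimeError(
                    f"failed generating pot {pot.uid} day {day}: {exc}"
                ) from exc
    paths = {
        "images": out / "images",
        "metadata": out / "metadata.csv",
        "ground_truth": out / "ground_truth.csv",
        "light_map": out / "light_map.csv",
    }
    pd.DataFrame(meta_rows).to_csv(paths["metadata"], index=False)
    pd.DataFrame(truth_rows).to_csv(paths["ground_truth"], index=False)
    base.to_csv(paths["light_map"], index=False)
    return paths


def _hsb_from_rgb(rgb: np.ndarray) -> np.ndarray:
    import matplotlib.colors as mcolors

    return mcolors.rgb_to_hsv(np.clip(rgb, 0, 255) / 255.0) * 255.0


def simulate_descriptor_table(
    layout: ExperimentLayout,
    light_map: list[LightPoint],
    morphotypes: dict[str, Morphotype],
    schedule: list[int],
    seed: int,
    gradient_config: GradientConfig | None = None,
    calibration_mm_per_px: float = 2.0,
) -> pd.DataFrame:
    """Descriptor table drawn from morphotype means + noise, no rendering.

    Dimension descriptors get mean-preserving multiplicative log-normal
    noise (the morphotype's ``noise_cv``); color channels get additive
    Gaussian noise clipped to [0, 255]; shape factors additive Gaussian
    clipped to (0, 1]. HSB statistics, vegetation indices and integrated
    density are derived from the noisy RGB/area values so internal
    consistency matches the image pipeline.
    """
    gcfg = gradient_config or GradientConfig()
    ln_min, ln_max = math.log(gcfg.min_ratio), math.log(gcfg.max_ratio)
    rng = np.random.default_rng(seed)
    by_uid = {lp.pot_uid: lp for lp in light_map}
    dims = ["side_HeightMax", "side_WidthMax", "side_AreaMean",
            "top_Area", "top_MeanFeret", "Voxel"]
    shapes = [c for c in desc.DESCRIPTOR_CLASSES["shape"]]
    rows = []
    for pot in layout.pots:
        m = morphotypes[pot.species]
        lp = by_uid[pot.uid]
        lnr = math.log(lp.ratio)
        sigma = math.sqrt(math.log1p(m.noise_cv ** 2))
        for day in schedule:
            def mean(col: str) -> float:
                return m.descriptor_mean(col, day, lnr, ln_min, ln_max)

            row: dict[str, float | str | int] = {
                "pot_uid": pot.uid, "species": pot.species, "room": pot.room,
                "row": pot.row, "column": pot.column,
                "ratio": lp.ratio, "ppfd": lp.ppfd, "day": day,
            }
            for col in dims:
                row[col] = mean(col) * math.exp(
                    rng.normal(-sigma * sigma / 2.0, sigma))
            for col in shapes:
                row[col] = float(np.clip(
                    mean(col) + rng.normal(0, m.shape_noise_sd), 1e-3, 1.0))
            for prefix in ("side", "top"):
                rgb = np.array([
                    mean(f"{prefix}_RedMean"), mean(f"{prefix}_GreenMean"),
                    mean(f"{prefix}_BlueMean"),
                ])
                rgb = np.clip(rgb + rng.normal(0, m.color_noise_sd, 3), 0, 255)
                hsb = _hsb_from_rgb(rgb)
                row[f"{prefix}_RedMean"] = rgb[0]
                row[f"{prefix}_GreenMean"] = rgb[1]
                row[f"{prefix}_BlueMean"] = rgb[2]
                row[f"{prefix}_HueMean"] = hsb[0]
                row[f"{prefix}_SaturationMean"] = hsb[1]
                row[f"{prefix}_BrightnessMean"] = hsb[2]
                row[f"{prefix}_HueCv"] = mean(f"{prefix}_HueCv") * math.exp(
                    rng.normal(0, 0.1))
                area = row["side_AreaMean" if prefix == "side" else "top_Area"]
                n_px = float(area) / calibration_mm_per_px ** 2
                row[f"{prefix}_Density"] = n_px * float(rgb.mean())
            idx = desc.color_indices(
                row["top_RedMean"], row["top_GreenMean"], row["top_BlueMean"])
            row["top_GLI"] = idx["GLI"]
            row["top_TGI"] = idx["TGI"]
            row["top_Chl_predicted"] = idx["Chl_predicted"]
            rows.append(row)
    return pd.DataFrame(rows)
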