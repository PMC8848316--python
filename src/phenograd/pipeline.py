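"""File-level plumbing joining generation → imaging → descriptors → analysis.

``process_experiment`` walks a run directory (images + metadata CSV),
segments and measures every pot×day, and returns the long descriptor table;
``analyze_experiment`` joins that table to the light map and produces the
effects table and PCA results. Failures are isolated per pot×day and
logged — one corrupt image never aborts a batch.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import descriptors as desc
from .config import RunConfig
from .gradient import effect_time_course
from .imaging import ImageRecord, PlantMask, SIDE, TOP, segment
from .multivariate import FeatureSelection, PCADiscrimination, pca_discriminate

log = logging.getLogger("phenograd")

__all__ = ["process_experiment", "analyze_experiment", "PCA_SELECTIONS"]

#: the standard grid of descriptor-class × view selections
PCA_SELECTIONS: dict[str, FeatureSelection] = {
    "full": FeatureSelection(),
    "dimensions": FeatureSelection(classes=("dimensions",)),
    "shape": FeatureSelection(classes=("shape",)),
    "color": FeatureSelection(classes=("color",)),
    "side": FeatureSelection(views=("side",)),
    "top": FeatureSelection(views=("top",)),
}


def _load_record(path: Path, pot_uid: str, view: str, frame: int, day: int,
                 mm_per_px: float) -> ImageRecord:
    with Image.open(path) as im:
        pixels = np.asarray(im.convert("RGB"))
    return ImageRecord(pixels=pixels, pot_uid=pot_uid, view=view,
                       frame_index=frame, day=day, calibration=mm_per_px)


def process_experiment(
    run_dir: str | Path,
    config: RunConfig | None = None,
    *,
    max_failure_fraction: float = 0.10,
) -> pd.DataFrame:
    """Measure every pot × day of a generated run into a descriptor table.

    Expects ``<run_dir>/images/<potUID>_<day>_<view>_<frame>.png`` and
    ``<run_dir>/metadata.csv``. Pots×days whose images are unreadable are
    skipped with a log entry; if more than ``max_failure_fraction`` of them
    fail, a ``RuntimeError`` is raised.
    """
    cfg = config or RunConfig()
    run = Path(run_dir)
    meta = pd.read_csv(run / "metadata.csv")
    images = run / "images"
    ignore = [cfg.render_config().chart_bbox] if cfg.chart else None
    rows: list[desc.DescriptorVector] = []
    failures = 0
    for _, m in meta.iterrows():
        pot_uid, day = str(m["pot_uid"]), int(m["day"])
        safe = pot_uid.replace(":", "-")
        try:
            side_vms = []
            for k in range(6):
                rec = _load_record(images / f"{safe}_{day}_side_{k}.png",
                                   pot_uid, SIDE, k, day, cfg.mm_per_px)
                mask = segment(rec, "grey", min_area=cfg.min_area_px,
                               ignore_regions=ignore)
                side_vms.append(desc.measure_view(rec, mask))
            rec = _load_record(images / f"{safe}_{day}_top_0.png",
                               pot_uid, TOP, 0, day, cfg.mm_per_px)
            mask = segment(rec, "color", min_area=cfg.min_area_px,
                           ignore_regions=ignore)
            top_vm = desc.measure_view(rec, mask)
            dv = desc.aggregate_views(
                side_vms, top_vm, pot_uid=pot_uid,
                species=str(m.get("species", "")), day=day,
                ratio=float(m.get("ratio", math.nan)),
            )
            fg = sum(int(v.area / cfg.mm_per_px ** 2) for v in side_vms)
            log.info("pot %s day %d: %d side fg px, flags=%s",
                     pot_uid, day, fg, dv.flags or "-")
            rows.append(dv)
        except Exception as exc:  # isolate per pot x day
            failures += 1
            log.warning("pot %s day %d failed: %s", pot_uid, day, exc)
    if len(meta) and failures / len(meta) > max_failure_fraction:
        raise RuntimeError(
            f"{failures}/{len(meta)} pot-days failed processing")
    return desc.descriptor_frame(rows)


def analyze_experiment(
    descriptor_table: pd.DataFrame,
    light_table: pd.DataFrame | None = None,
    config: RunConfig | None = None,
    descriptors: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, PCADiscrimination]]:
    """Gradient effects table + the PCA selection grid.

    ``light_table`` (pot_uid → ratio) is joined on pot_uid when the
    descriptor table lacks a ratio column; UID mismatches raise with the
    offending UIDs listed.
    """
    cfg = config or RunConfig()
    df = descriptor_table
    if "ratio" not in df.columns or df["ratio"].isna().all():
        if light_table is None:
            raise ValueError("no ratio column and no light table to join")
        lt = light_table[["pot_uid", "ratio"]]
        missing = set(df["pot_uid"]) - set(lt["pot_uid"])
        if missing:
            raise ValueError(
                f"pot UIDs missing from light table: {sorted(missing)[:10]}")
        df = df.drop(columns=["ratio"], errors="ignore").merge(
            lt, on="pot_uid", how="left")
    names = descriptors or [c for c in desc.DESCRIPTOR_COLUMNS if c in df]
    effects = effect_time_course(
        df, names, baseline=cfg.effect_baseline,
        treatment_end=cfg.treatment_end, fdr=cfg.fdr,
    )
    pca_results: dict[str, PCADiscrimination] = {}
    window = (cfg.pca_day_min, cfg.pca_day_max)
    for label, sel in PCA_SELECTIONS.items():
        sel_w = FeatureSelection(sel.classes, sel.views, window)
        try:
            pca_results[label] = pca_discriminate(
                df, sel_w, exclude_side_for=tuple(cfg.exclude_side_for))
        except ValueError as exc:
            log.warning("PCA selection %s skipped: %s", label, exc)
    return effects, pca_results
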