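"""Raw RGB frames to calibrated, segmented plant masks.

The imaging chain mirrors a standard phenotyping-cabinet workflow: each pot
is photographed six times from the side during a 180° rotation (plant in
front of a diffusive back-lit white background) and once from the top
(plant over a black cloth). Frames are white-balanced and spatially
calibrated against a reference color chart, then segmented by grey-scale
(side) or excess-green color (top) thresholding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from skimage import filters, morphology

__all__ = [
    "ImageRecord",
    "ColorReference",
    "PlantMask",
    "CalibrationError",
    "white_balance",
    "spatial_calibration",
    "segment",
]

SIDE = "side"
TOP = "top"


class CalibrationError(ValueError):
    """Color chart missing, occluded or geometrically invalid."""


@dataclass
class ImageRecord:
    """One 8-bit RGB frame plus acquisition metadata.

    ``frame_index`` runs 0–5 for the side views (30° rotation steps over
    180°) and is 0 for the single top view. ``calibration`` is mm per pixel,
    unset until spatial calibration has run.
    """

    pixels: np.ndarray
    pot_uid: str = ""
    view: str = SIDE
    frame_index: int = 0
    day: int = 0
    calibration: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an H x W x 3 array")
        if self.view == SIDE and not 0 <= self.frame_index < 6:
            raise ValueError("side views carry frame_index 0..5")


@dataclass
class ColorReference:
    """Reference chart: where the neutral patch sits and how big it is.

    ``patch_bbox`` is (row0, col0, row1, col1) in pixels (exclusive stop);
    ``nominal_rgb`` the patch's nominal color; ``patch_size_mm`` its physical
    edge length, used for spatial calibration.
    """

    patch_bbox: tuple[int, int, int, int]
    nominal_rgb: tuple[float, float, float] = (200.0, 200.0, 200.0)
    patch_size_mm: float = 20.0

    def __post_init__(self) -> None:
        r0, c0, r1, c1 = self.patch_bbox
        if r1 <= r0 or c1 <= c0:
            raise CalibrationError("degenerate chart patch bbox")
        if self.patch_size_mm <= 0:
            raise CalibrationError("chart patch physical size must be > 0")
        lo, hi = min(self.nominal_rgb), max(self.nominal_rgb)
        if hi - lo > 10:
            raise CalibrationError("reference patch must be neutral (grey)")


@dataclass
class PlantMask:
    """Binary plant segmentation with its mm-per-pixel calibration."""

    pixels: np.ndarray
    calibration: float = 1.0
    view: str = SIDE
    pot_uid: str = ""
    day: int = 0
    empty: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        self.empty = not bool(self.pixels.any())


def _patch_means(image: ImageRecord, ref: ColorReference) -> np.ndarray:
    r0, c0, r1, c1 = ref.patch_bbox
    h, w = image.pixels.shape[:2]
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
        raise CalibrationError(
            f"chart patch {ref.patch_bbox} outside {h}x{w} frame"
        )
    patch = image.pixels[r0:r1, c0:c1].astype(float)
    means = patch.reshape(-1, 3).mean(axis=0)
    if means.min() < 5 or means.max() > 250:
        raise CalibrationError(
            f"chart patch saturated or dark (channel means {means.round(1)})"
        )
    return means


def white_balance(image: ImageRecord, ref: ColorReference) -> ImageRecord:
    """Equalize the neutral patch's channel means by per-channel gains.

    Each channel is scaled so the grey patch reads the same in R, G and B
    (their common mean); output is clipped back to [0, 255]. Idempotent
    within rounding.
    """
    means = _patch_means(image, ref)
    target = means.mean()
    gains = target / means
    balanced = np.clip(image.pixels.astype(float) * gains, 0, 255)
    return replace(image, pixels=balanced.astype(np.uint8))


def spatial_calibration(ref: ColorReference, detected_size_px: float) -> float:
    """mm-per-pixel scale from the detected chart patch size.

    calibration = physical patch edge (mm) / detected edge (px).
    """
    if detected_size_px <= 0:
        raise CalibrationError("detected patch size must be > 0 px")
    return ref.patch_size_mm / detected_size_px


def _foreground_score(image: ImageRecord, method: str) -> np.ndarray:
    rgb = image.pixels.astype(float)
    if method == "grey":
        # dark plant on a back-lit white background: invert brightness
        return 255.0 - rgb.mean(axis=2)
    if method == "color":
        # excess green (2G - R - B): green plant on dark cloth
        return 2.0 * rgb[..., 1] - rgb[..., 0] - rgb[..., 2]
    raise ValueError(f"unknown segmentation method {method!r}")


def segment(
    image: ImageRecord,
    method: str | None = None,
    *,
    threshold: float | None = None,
    min_area: int = 25,
    ignore_regions: list[tuple[int, int, int, int]] | None = None,
) -> PlantMask:
    """Threshold the plant from the background.

    ``method`` defaults to ``"grey"`` (inverted brightness, Otsu) for side
    views and ``"color"`` (excess green, Otsu) for top views; a fixed
    ``threshold`` overrides Otsu. Connected components smaller than
    ``min_area`` pixels are dropped, but all larger ones are kept (multi-
    plant pots are one specimen). ``ignore_regions`` (row0, col0, row1, col1)
    boxes — e.g. the color chart — are excluded before thresholding. An
    image with no plant returns an *empty, flagged* mask, not an error.
    """
    if method is None:
        method = "grey" if image.view == SIDE else "color"
    score = _foreground_score(image, method)
    valid = np.ones(score.shape, dtype=bool)
    for r0, c0, r1, c1 in ignore_regions or []:
        valid[r0:r1, c0:c1] = False
    if threshold is None:
        vals = score[valid]
        # degenerate (uniform) image: nothing to segment
        if vals.max() - vals.min() < 1e-9:
            fg = np.zeros(score.shape, dtype=bool)
        else:
            thr = filters.threshold_otsu(vals)
            fg = (score > thr) & valid
            # Otsu on a plant-free frame splits noise; reject masks whose
            # foreground/background contrast is negligible
            if fg.any() and (vals.max() - thr) < 10:
                fg = np.zeros(score.shape, dtype=bool)
    else:
        fg = (score > threshold) & valid
    if fg.any() and min_area > 1:
        labels, n = morphology.label(fg, return_num=True)
        if n:
            sizes = np.bincount(labels.ravel())
            sizes[0] = 0
            fg = sizes[labels] >= min_area
    cal = image.calibration if image.calibration else 1.0
    return PlantMask(
        pixels=fg, calibration=cal, view=image.view,
        pot_uid=image.pot_uid, day=image.day,
    )
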