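"""LGE signal-intensity threshold segmentation.

Myocardium is partitioned relative to the maximum signal in a small core
ROI of the focal-fibrosis region: non-enhanced below 20 % of the maximum,
intermediate in [20 %, 50 %), enhanced at or above 50 % (the FWHM
convention includes the half-maximum in the enhanced class).  The exact
20 % / 50 % boundary assignment is a documented convention; the source
thresholds name only open intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "LgeImage",
    "EnhancementMask",
    "CLASS_CODES",
    "locate_core_max_si",
    "classify_enhancement",
    "transfer_threshold",
    "extract_roi",
    "auto_core_roi",
]

THRESHOLDS = (0.20, 0.50)

CLASS_CODES = {
    "outside": 0,
    "non_enhanced": 1,
    "intermediate": 2,
    "enhanced": 3,
}
_CODE_NAMES = {v: k for k, v in CLASS_CODES.items()}


@dataclass
class LgeImage:
    """Magnitude LGE slice with its myocardial mask."""

    pixels: np.ndarray
    myocardial_mask: np.ndarray
    pixel_spacing: float = 2.0  # mm

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.myocardial_mask = np.asarray(self.myocardial_mask, dtype=bool)
        if self.pixels.shape != self.myocardial_mask.shape:
            raise ValueError("image and mask shapes differ")
        if np.any(self.pixels < 0):
            raise ValueError("magnitude image cannot be negative")
        if not self.myocardial_mask.any():
            raise ValueError("myocardial mask is empty")


@dataclass
class EnhancementMask:
    """Three-class labeling of the myocardium plus the reference max SI."""

    classes: np.ndarray  # CLASS_CODES per pixel
    max_si: float
    thresholds: tuple[float, float] = THRESHOLDS

    def pixels_of(self, class_name: str) -> np.ndarray:
        return self.classes == CLASS_CODES[class_name]

    def class_counts(self) -> dict:
        return {
            name: int((self.classes == code).sum())
            for name, code in CLASS_CODES.items()
            if name != "outside"
        }


def locate_core_max_si(image: LgeImage, core_roi: np.ndarray) -> float:
    """Maximum pixel value inside the lesion-core ROI."""
    roi = np.asarray(core_roi, dtype=bool)
    if not roi.any():
        raise ValueError("core ROI is empty")
    if np.any(roi & ~image.myocardial_mask):
        raise ValueError("core ROI extends outside the myocardial mask")
    return float(image.pixels[roi].max())


def auto_core_roi(
    region_map: np.ndarray, core_code: int, size: int = 3
) -> np.ndarray:
    """3x3 ROI centered on the centroid of the ground-truth lesion core.

    Synthetic-pipeline stand-in for the manually drawn small core ROI.
    """
    core = np.asarray(region_map) == core_code
    if not core.any():
        raise ValueError("no lesion core in region map")
    cy, cx = ndimage.center_of_mass(core)
    # snap the centroid into the core (annular sectors are non-convex)
    if not core[int(round(cy)), int(round(cx))]:
        ys, xs = np.nonzero(core)
        k = np.argmin((ys - cy) ** 2 + (xs - cx) ** 2)
        cy, cx = ys[k], xs[k]
    half = size // 2
    roi = np.zeros(core.shape, dtype=bool)
    y0, x0 = int(round(cy)), int(round(cx))
    roi[
        max(0, y0 - half) : y0 + half + 1, max(0, x0 - half) : x0 + half + 1
    ] = True
    return roi & core


def classify_enhancement(image: LgeImage, max_si: float) -> EnhancementMask:
    """Partition the myocardium by SI relative to ``max_si``.

    ratio < 0.20 -> non_enhanced; 0.20 <= ratio < 0.50 -> intermediate;
    ratio >= 0.50 -> enhanced; pixels outside the mask -> outside.
    """
    if max_si <= 0:
        raise ValueError("max_si must be positive")
    ratio = image.pixels / max_si
    classes = np.zeros(image.pixels.shape, dtype=np.uint8)
    m = image.myocardial_mask
    classes[m & (ratio < THRESHOLDS[0])] = CLASS_CODES["non_enhanced"]
    classes[m & (ratio >= THRESHOLDS[0]) & (ratio < THRESHOLDS[1])] = CLASS_CODES[
        "intermediate"
    ]
    classes[m & (ratio >= THRESHOLDS[1])] = CLASS_CODES["enhanced"]
    return EnhancementMask(classes=classes, max_si=float(max_si))


def transfer_threshold(
    reference_image: LgeImage,
    reference_core_roi: np.ndarray,
    target_image: LgeImage,
) -> EnhancementMask:
    """Classify a target slice with the max SI taken from a reference slice.

    Used when the enhancement lies on a different slice than the one being
    analyzed; both slices must share intensity normalization.
    """
    max_si = locate_core_max_si(reference_image, reference_core_roi)
    return classify_enhancement(target_image, max_si)


def extract_roi(
    mask: EnhancementMask, target_class: str, min_area: int = 1
) -> np.ndarray:
    """Largest 8-connected component of a class with area >= ``min_area``.

    Returns an all-False mask when no component qualifies.
    """
    if target_class not in CLASS_CODES or target_class == "outside":
        raise ValueError(f"invalid target class {target_class!r}")
    sel = mask.pixels_of(target_class)
    labeled, n = ndimage.label(sel, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return np.zeros(sel.shape, dtype=bool)
    sizes = ndimage.sum_labels(sel, labeled, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < min_area:
        return np.zeros(sel.shape, dtype=bool)
    return labeled == best
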