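"""AHA six-segment analysis of the mid-ventricular short-axis slice.

The mid-cavity ring is divided into six 60-degree wedges anchored at the
anterior RV insertion point.  Wedge index 0 starts at the insertion angle
and indices increase with the image-plane angle; the label order follows
the mid-cavity convention (anteroseptal, inferoseptal, inferior,
inferolateral, anterolateral, anterior).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

__all__ = [
    "SEGMENT_NAMES",
    "LvContours",
    "SegmentSet",
    "divide_aha6",
    "wall_thickness",
    "classify_hypertrophic",
    "lv_mass_indexed",
    "contours_from_geometry",
]

# wedge index (from the anterior RV insertion, increasing angle) -> name
SEGMENT_NAMES = (
    "anteroseptal",
    "inferoseptal",
    "inferior",
    "inferolateral",
    "anterolateral",
    "anterior",
)

HYPERTROPHY_THRESHOLD_MM = 15.0
MYOCARDIAL_DENSITY_G_PER_ML = 1.05


@dataclass
class LvContours:
    """Endo/epicardial contours per slice in mm coordinates."""

    endo: list  # list of (N, 2) arrays per slice
    epi: list
    slice_thickness: float  # mm
    slice_gap: float = 0.0  # mm
    rv_insertion_angle: float = 120.0  # deg

    def __post_init__(self) -> None:
        if len(self.endo) != len(self.epi):
            raise ValueError("endo and epi contour counts differ")
        if not self.endo:
            raise ValueError("at least one slice required")


@dataclass
class SegmentSet:
    """Six segment masks plus per-segment wall thickness and flags."""

    masks: dict  # name -> bool array
    wall_thickness_mm: dict = field(default_factory=dict)
    hypertrophic: dict = field(default_factory=dict)

    def partition_ok(self, myocardial_mask: np.ndarray) -> bool:
        total = np.zeros(myocardial_mask.shape, dtype=int)
        for m in self.masks.values():
            total += m.astype(int)
        return bool(
            np.array_equal(total > 0, np.asarray(myocardial_mask, dtype=bool))
            and total.max() <= 1
        )


def divide_aha6(
    mask: np.ndarray,
    centroid: tuple[float, float] | None = None,
    rv_insertion_angle: float = 120.0,
) -> SegmentSet:
    """Assign every myocardial pixel to one of six 60-degree wedges.

    Angles are measured in the image plane (atan2 of pixel offsets from
    the cavity centroid) and counted from ``rv_insertion_angle``.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 6:
        raise ValueError("degenerate myocardial mask")
    ys, xs = np.nonzero(mask)
    if centroid is None:
        centroid = (float(ys.mean()), float(xs.mean()))
    cy, cx = centroid
    angle = np.degrees(np.arctan2(ys - cy, xs - cx)) % 360.0
    wedge = ((angle - rv_insertion_angle) % 360.0 // 60.0).astype(int)
    masks = {}
    for w, name in enumerate(SEGMENT_NAMES):
        m = np.zeros(mask.shape, dtype=bool)
        m[ys[wedge == w], xs[wedge == w]] = True
        masks[name] = m
    return SegmentSet(masks=masks)


def _contour_radius(contour: np.ndarray, center: np.ndarray, angles_deg: np.ndarray) -> np.ndarray:
    """Radius of a closed contour at the requested polar angles."""
    pts = np.asarray(contour, dtype=float) - center
    theta = np.degrees(np.arctan2(pts[:, 1], pts[:, 0])) % 360.0
    r = np.hypot(pts[:, 0], pts[:, 1])
    order = np.argsort(theta)
    theta, r = theta[order], r[order]
    # periodic linear interpolation
    theta_ext = np.concatenate([theta - 360.0, theta, theta + 360.0])
    r_ext = np.concatenate([r, r, r])
    return np.interp(angles_deg, theta_ext, r_ext)


def wall_thickness(
    contours: LvContours, segment: str, slice_index: int = 0, n_rays: int = 360
) -> float:
    """Mean epi-endo radial distance over the segment's angular sector."""
    if segment not in SEGMENT_NAMES:
        raise ValueError(f"unknown segment {segment!r}")
    endo = np.asarray(contours.endo[slice_index], dtype=float)
    epi = np.asarray(contours.epi[slice_index], dtype=float)
    center = endo.mean(axis=0)
    w = SEGMENT_NAMES.index(segment)
    a0 = contours.rv_insertion_angle + 60.0 * w
    angles = (a0 + np.linspace(0.0, 60.0, n_rays, endpoint=False)) % 360.0
    r_endo = _contour_radius(endo, center, angles)
    r_epi = _contour_radius(epi, center, angles)
    thickness = r_epi - r_endo
    if np.any(thickness <= 0):
        raise ValueError("epicardial contour crosses endocardial contour")
    return float(thickness.mean())


def max_wall_thickness(contours: LvContours, slice_index: int = 0) -> float:
    """Maximum per-segment wall thickness on a slice."""
    return max(
        wall_thickness(contours, name, slice_index) for name in SEGMENT_NAMES
    )


def classify_hypertrophic(
    thickness_mm: float, threshold_mm: float = HYPERTROPHY_THRESHOLD_MM
) -> bool:
    """Hypertrophic iff wall thickness >= threshold (15 mm, inclusive)."""
    if thickness_mm <= 0:
        raise ValueError("thickness must be positive")
    return bool(thickness_mm >= threshold_mm)


def lv_mass_indexed(contours: LvContours, bsa: float) -> tuple[float, float]:
    """(mass_g, mass_indexed_g_per_m2) from stacked contour areas.

    Per slice: (epi area - endo area) * (slice thickness + gap) * 1.05 g/mL;
    summed over slices and divided by body surface area.
    """
    if bsa <= 0:
        raise ValueError("BSA must be positive")
    depth_mm = contours.slice_thickness + contours.slice_gap
    volume_mm3 = 0.0
    for endo, epi in zip(contours.endo, contours.epi):
        a_endo = Polygon(np.asarray(endo)).area
        a_epi = Polygon(np.asarray(epi)).area
        ring = a_epi - a_endo
        if ring <= 0:
            raise ValueError("non-positive myocardial ring area")
        volume_mm3 += ring * depth_mm
    mass_g = volume_mm3 / 1000.0 * MYOCARDIAL_DENSITY_G_PER_ML
    return mass_g, mass_g / bsa


def contours_from_geometry(geometry, n_points: int = 720) -> LvContours:
    """Analytic endo/epi contours of a phantom geometry (mm, single slice)."""
    theta = np.linspace(0.0, 360.0, n_points, endpoint=False)
    rad = np.radians(theta)
    endo = np.column_stack(
        [geometry.endo_radius * np.cos(rad), geometry.endo_radius * np.sin(rad)]
    )
    r_epi = geometry.epi_radius_at(theta)
    epi = np.column_stack([r_epi * np.cos(rad), r_epi * np.sin(rad)])
    return LvContours(
        endo=[endo],
        epi=[epi],
        slice_thickness=8.0,
        slice_gap=0.0,
        rv_insertion_angle=geometry.rv_insertion_angle,
    )
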