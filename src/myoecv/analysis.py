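"""Subject-level analysis: render -> register -> fit T1 -> segment LGE ->
ECV per ROI / SI class / AHA segment.

These functions operate on in-memory :class:`SyntheticSubject` bundles (or
user-supplied data shaped like them) and are what the disk-level pipeline,
the test-suite oracles and the acceptance runs all share.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import lge as lge_mod
from .ecv import EcvResult, auto_blood_roi, ecv_for_roi
from .lge import LgeImage, auto_core_roi, classify_enhancement, extract_roi, locate_core_max_si
from .relaxometry import T1Map, compute_t1_map, register_frames
from .segments import (
    SEGMENT_NAMES,
    classify_hypertrophic,
    contours_from_geometry,
    divide_aha6,
    lv_mass_indexed,
    max_wall_thickness,
    wall_thickness,
)
from .synthetic import REGION_LABELS, SyntheticSubject

__all__ = [
    "SubjectAnalysis",
    "fit_subject_t1_maps",
    "analyze_subject",
]

MIN_ROI_AREA = 4  # pixels; smallest component accepted as an analysis ROI


@dataclass
class SubjectAnalysis:
    """Everything the pipeline measures for one subject."""

    subject_id: str
    group_label: str
    lge_positive: bool
    ecv_global: EcvResult | None = None
    ecv_by_class: dict = field(default_factory=dict)  # class -> EcvResult
    ecv_by_segment: dict = field(default_factory=dict)  # name -> EcvResult
    wall_thickness_mm: dict = field(default_factory=dict)
    hypertrophic: dict = field(default_factory=dict)
    max_wall_thickness_mm: float | None = None
    lv_mass_g: float | None = None
    lv_mass_indexed: float | None = None
    registration_shifts: dict = field(default_factory=dict)
    t1_maps: dict = field(default_factory=dict)


def fit_subject_t1_maps(
    subject: SyntheticSubject, register: bool = False
) -> tuple[dict, dict]:
    """Fit the three T1 maps inside the blood+myocardium mask.

    Returns ``(t1_maps, shifts)`` keyed by time-point label.
    """
    fit_mask = subject.myocardium_mask | subject.blood_mask
    t1_maps: dict[str, T1Map] = {}
    shifts: dict[str, np.ndarray] = {}
    for label, series in subject.molli.items():
        if register:
            series, shift = register_frames(series)
            shifts[label] = shift
        t1_maps[label] = compute_t1_map(series, fit_mask)
    return t1_maps, shifts


def _class_rois(subject: SyntheticSubject) -> dict:
    """SI-class analysis ROIs from the LGE threshold algorithm.

    The core max SI is auto-located at the ground-truth lesion-core
    centroid (synthetic stand-in for the manually drawn small ROI).  Each
    class ROI is drawn *within* its area: the largest connected component
    of the class, eroded one pixel to avoid boundary and stray
    misclassified pixels (skipped when erosion would drop the ROI below
    the minimum area).
    """
    from scipy import ndimage

    image = LgeImage(
        pixels=subject.lge_image,
        myocardial_mask=subject.myocardium_mask,
        pixel_spacing=subject.geometry.pixel_spacing,
    )
    core_roi = auto_core_roi(subject.region_map, REGION_LABELS["lesion_core"])
    max_si = locate_core_max_si(image, core_roi)
    mask = classify_enhancement(image, max_si)
    rois = {}
    for cls in ("non_enhanced", "intermediate", "enhanced"):
        comp = extract_roi(mask, cls, min_area=MIN_ROI_AREA)
        if not comp.any():
            continue
        interior = ndimage.binary_erosion(comp)
        rois[cls] = interior if interior.sum() >= MIN_ROI_AREA else comp
    return rois


def analyze_subject(
    subject: SyntheticSubject,
    register: bool = True,
    segmental: bool = False,
    t1_maps: dict | None = None,
) -> SubjectAnalysis:
    """Run the full measurement chain for one subject.

    Global ECV uses the whole myocardium for LGE-negative subjects and the
    largest non-enhanced component for LGE-positive ones.  ``segmental``
    adds per-AHA-segment ECV, wall thickness and hypertrophy flags.
    """
    result = SubjectAnalysis(
        subject_id=subject.subject_id,
        group_label=subject.group_label,
        lge_positive=subject.lge_positive,
    )
    if t1_maps is None:
        t1_maps, shifts = fit_subject_t1_maps(subject, register=register)
        result.registration_shifts = shifts
    result.t1_maps = t1_maps
    hct = subject.tissue.hematocrit
    blood_roi = auto_blood_roi(subject.blood_mask)

    if subject.lge_positive:
        rois = _class_rois(subject)
        for cls, roi in rois.items():
            result.ecv_by_class[cls] = ecv_for_roi(
                t1_maps, roi, blood_roi, hct, roi_id=cls
            )
        if "non_enhanced" in result.ecv_by_class:
            result.ecv_global = result.ecv_by_class["non_enhanced"]
    else:
        result.ecv_global = ecv_for_roi(
            t1_maps, subject.myocardium_mask, blood_roi, hct, roi_id="myocardium"
        )

    if segmental:
        segset = divide_aha6(
            subject.myocardium_mask,
            rv_insertion_angle=subject.geometry.rv_insertion_angle,
        )
        contours = contours_from_geometry(subject.geometry)
        for name in SEGMENT_NAMES:
            seg_mask = segset.masks[name]
            if not seg_mask.any():
                continue
            result.ecv_by_segment[name] = ecv_for_roi(
                t1_maps, seg_mask, blood_roi, hct, roi_id=name
            )
            wt = wall_thickness(contours, name)
            result.wall_thickness_mm[name] = wt
            result.hypertrophic[name] = classify_hypertrophic(wt)
        result.max_wall_thickness_mm = max_wall_thickness(contours)
        bsa = subject.covariates.get("bsa")
        if bsa:
            result.lv_mass_g, result.lv_mass_indexed = lv_mass_indexed(
                contours, bsa
            )
    return result
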