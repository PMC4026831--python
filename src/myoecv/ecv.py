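"""Partition-coefficient and extracellular-volume-fraction estimation.

T1 is converted to the relaxation rate R1 = 1000/T1 (ms -> s^-1), the
contrast partition coefficient is the ordinary-least-squares slope of
myocardial R1 on blood-pool R1 across the three acquisition time points,
and ECV applies the hematocrit correction ``ECV = lambda * (1 - Hct)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, stats

from .relaxometry import T1Map

__all__ = [
    "R1Sample",
    "PartitionFit",
    "EcvResult",
    "r1_from_t1",
    "fit_partition_coefficient",
    "compute_ecv",
    "ecv_for_roi",
    "auto_blood_roi",
]

TIME_POINTS = ("pre", "post8", "post20")


@dataclass(frozen=True)
class R1Sample:
    """Paired myocardial/blood relaxation rates at one time point."""

    time_point: str
    r1_myo: float
    r1_blood: float
    roi_id: str = "roi"

    def __post_init__(self) -> None:
        if self.r1_myo <= 0 or self.r1_blood <= 0:
            raise ValueError("relaxation rates must be positive")


@dataclass
class PartitionFit:
    """OLS slope of myocardial on blood R1 with fit diagnostics."""

    lambda_: float
    intercept: float
    r_squared: float
    n_points: int


@dataclass
class EcvResult:
    ecv: float
    lambda_: float
    intercept: float
    r_squared: float
    hematocrit: float
    roi_id: str = "roi"
    valid: bool = True


def r1_from_t1(t1_ms: float) -> float:
    """R1 in s^-1 from T1 in ms (explicit unit conversion)."""
    t1 = np.asarray(t1_ms, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("T1 must be positive")
    out = 1000.0 / t1
    return float(out) if out.ndim == 0 else out


def fit_partition_coefficient(samples: Sequence[R1Sample]) -> PartitionFit:
    """Least-squares regression of myocardial R1 on blood-pool R1.

    The regression keeps an intercept (rates, not rate changes, are
    regressed).  At least two samples with distinct blood R1 are required.
    """
    if len(samples) < 2:
        raise ValueError("at least two R1 samples required")
    blood = np.array([s.r1_blood for s in samples])
    myo = np.array([s.r1_myo for s in samples])
    if np.ptp(blood) == 0:
        raise ValueError("degenerate regression: all blood R1 identical")
    res = stats.linregress(blood, myo)
    return PartitionFit(
        lambda_=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(samples),
    )


def compute_ecv(fit: PartitionFit, hematocrit: float, roi_id: str = "roi") -> EcvResult:
    """Hematocrit-corrected ECV = lambda * (1 - Hct).

    Results outside (0, 1) are flagged invalid rather than rejected.
    """
    if not 0 < hematocrit < 1:
        raise ValueError("hematocrit must lie in (0, 1)")
    ecv = fit.lambda_ * (1.0 - hematocrit)
    return EcvResult(
        ecv=float(ecv),
        lambda_=fit.lambda_,
        intercept=fit.intercept,
        r_squared=fit.r_squared,
        hematocrit=hematocrit,
        roi_id=roi_id,
        valid=bool(0 < ecv < 1),
    )


def ecv_for_roi(
    t1_maps: dict,
    roi: np.ndarray,
    blood_roi: np.ndarray,
    hematocrit: float,
    roi_id: str = "roi",
) -> EcvResult:
    """ROI-level ECV from the three T1 maps.

    The ROI-mean T1 is computed per time point (valid pixels only), turned
    into R1, regressed against the blood-pool R1 and hematocrit-corrected.
    ``t1_maps`` maps the labels pre/post8/post20 to :class:`T1Map`.  The
    fit's R^2 doubles as a dynamic-equilibrium diagnostic.
    """
    samples = []
    for tp in TIME_POINTS:
        tmap: T1Map = t1_maps[tp]
        t1_roi = tmap.roi_mean(roi)
        t1_blood = tmap.roi_mean(blood_roi)
        if not np.isfinite(t1_roi) or not np.isfinite(t1_blood):
            raise ValueError(f"ROI has no valid pixels at time point {tp!r}")
        samples.append(
            R1Sample(
                time_point=tp,
                r1_myo=r1_from_t1(t1_roi),
                r1_blood=r1_from_t1(t1_blood),
                roi_id=roi_id,
            )
        )
    fit = fit_partition_coefficient(samples)
    return compute_ecv(fit, hematocrit, roi_id=roi_id)


def auto_blood_roi(blood_mask: np.ndarray, erode_px: int = 2) -> np.ndarray:
    """Central blood-pool ROI: the cavity mask eroded away from the wall.

    Emulates a ROI at the center of the LV blood pool while avoiding
    partial-volume pixels at the endocardial border.
    """
    mask = np.asarray(blood_mask, dtype=bool)
    if not mask.any():
        raise ValueError("blood mask is empty")
    eroded = ndimage.binary_erosion(mask, iterations=erode_px) if erode_px else mask
    return eroded if eroded.any() else mask
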