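"""Disk serialization: NIfTI image stacks, JSON sidecars, provenance.

Per subject the simulate stage writes ``<id>_molli_t{0,8,20}.nii.gz``
(11-frame stacks), ``<id>_lge.nii.gz``, ``<id>_masks.nii.gz`` (two
volumes: blood/myocardium coding and ground-truth region classes) and
``<id>_truth.json``; the cohort table is ``cohort.csv``.  Every JSON
artifact carries a provenance block (package version, config hash, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import nibabel as nib
import numpy as np

from . import __version__
from .relaxometry import MolliSeries, T1Map
from .synthetic import (
    LesionSector,
    PhantomGeometry,
    SyntheticSubject,
    TissueModel,
)

__all__ = [
    "dump_json",
    "provenance_block",
    "config_hash",
    "save_subject",
    "load_subject",
    "save_t1_map",
    "load_t1_map",
]

MOLLI_SUFFIX = {"pre": "molli_t0", "post8": "molli_t8", "post20": "molli_t20"}
_LABEL_OF = {v: k for k, v in MOLLI_SUFFIX.items()}


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def dump_json(payload: dict, path: Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, default=_json_default))


def config_hash(config: dict) -> str:
    """Stable sha256 of a JSON-serializable configuration."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def provenance_block(seed: int, config: dict | None = None) -> dict:
    return {
        "artifact_version": __version__,
        "seed": seed,
        "config_hash": config_hash(config or {}),
        "created": datetime.now(timezone.utc).isoformat(timespec="seconds"),
    }


def _save_nii(data: np.ndarray, path: Path, pixel_spacing: float) -> None:
    affine = np.diag([pixel_spacing, pixel_spacing, 1.0, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def _load_nii(path: Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=float)


def save_subject(
    subject: SyntheticSubject, outdir: Path, provenance: dict | None = None
) -> None:
    """Write one subject's image stacks, masks and ground-truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sp = subject.geometry.pixel_spacing
    sid = subject.subject_id
    for label, series in subject.molli.items():
        # frames stored as (ny, nx, n_frames) volumes
        _save_nii(
            np.moveaxis(series.frames, 0, -1),
            outdir / f"{sid}_{MOLLI_SUFFIX[label]}.nii.gz",
            sp,
        )
    _save_nii(subject.lge_image, outdir / f"{sid}_lge.nii.gz", sp)
    masks = np.stack([subject.masks, subject.region_map], axis=-1)
    _save_nii(masks, outdir / f"{sid}_masks.nii.gz", sp)

    sidecar = subject.truth_sidecar()
    sidecar["geometry"] = asdict(subject.geometry)
    sidecar["tissue"] = asdict(subject.tissue)
    sidecar["segment_lambda"] = subject.segment_lambda
    sidecar["rr_interval"] = next(iter(subject.molli.values())).rr_interval
    if provenance:
        sidecar["provenance"] = provenance
    dump_json(sidecar, outdir / f"{sid}_truth.json")


def load_subject(outdir: Path, subject_id: str) -> SyntheticSubject:
    """Reconstruct a subject bundle from its serialized form."""
    outdir = Path(outdir)
    sidecar = json.loads((outdir / f"{subject_id}_truth.json").read_text())
    geo_d = dict(sidecar["geometry"])
    geo_d["lesion_sectors"] = [LesionSector(**s) for s in geo_d["lesion_sectors"]]
    geo_d["thick_sectors"] = [tuple(t) for t in geo_d["thick_sectors"]]
    geometry = PhantomGeometry(**geo_d)
    tis_d = dict(sidecar["tissue"])
    tis_d["washout_amplitudes"] = tuple(tis_d["washout_amplitudes"])
    tis_d["washout_rates"] = tuple(tis_d["washout_rates"])
    tissue = TissueModel(**tis_d)

    masks4 = _load_nii(outdir / f"{subject_id}_masks.nii.gz")
    masks = masks4[..., 0].astype(np.uint8)
    region_map = masks4[..., 1].astype(np.uint8)

    seg_lambda = sidecar.get("segment_lambda")
    if seg_lambda:
        seg_lambda = {int(k): float(v) for k, v in seg_lambda.items()}
    subject = SyntheticSubject(
        subject_id=subject_id,
        group_label=sidecar["group_label"],
        lge_positive=sidecar["lge_positive"],
        geometry=geometry,
        tissue=tissue,
        covariates=sidecar.get("covariates", {}),
        ground_truth_ecv=sidecar["ground_truth_ecv"],
        region_map=region_map,
        masks=masks,
        segment_lambda=seg_lambda,
        time_points_min=tuple(sidecar["time_points_min"]),
    )
    for label, suffix in MOLLI_SUFFIX.items():
        path = outdir / f"{subject_id}_{suffix}.nii.gz"
        if not path.exists():
            continue
        frames = np.moveaxis(_load_nii(path), -1, 0)
        subject.molli[label] = MolliSeries(
            frames=frames,
            effective_tis=np.asarray(sidecar["effective_tis"][label]),
            time_point_label=label,
            rr_interval=sidecar.get("rr_interval", 1000.0),
        )
    lge_path = outdir / f"{subject_id}_lge.nii.gz"
    if lge_path.exists():
        subject.lge_image = _load_nii(lge_path)
        subject.lge_ti = sidecar.get("lge_ti_ms")
    return subject


def save_t1_map(tmap: T1Map, path: Path, pixel_spacing: float = 2.0) -> None:
    """T1 map + validity + residual diagnostics as a 3-volume NIfTI."""
    stack = np.stack(
        [tmap.t1, tmap.validity_mask.astype(float), tmap.fit_diagnostics], axis=-1
    )
    _save_nii(stack, Path(path), pixel_spacing)


def load_t1_map(path: Path) -> T1Map:
    stack = _load_nii(Path(path))
    return T1Map(
        t1=stack[..., 0],
        validity_mask=stack[..., 1] > 0.5,
        fit_diagnostics=stack[..., 2],
    )
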