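"""Disk-level pipeline: simulate -> fit T1 -> segment LGE -> ECV ->
segments -> report, with per-subject failure isolation and provenance.

Each stage reads only prior-stage outputs from the run directory and
writes its own artifacts there; a subject failing one stage is logged
and skipped, not fatal for the cohort.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import analyze_subject, fit_subject_t1_maps
from .config import RunConfig
from .io import (
    MOLLI_SUFFIX,
    dump_json,
    load_subject,
    load_t1_map,
    provenance_block,
    save_subject,
    save_t1_map,
)
from .lge import (
    LgeImage,
    auto_core_roi,
    classify_enhancement,
    locate_core_max_si,
)
from .stats import anova_bonferroni, compare_groups, proportion_test
from .synthetic import REGION_LABELS, generate_cohort

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger("myoecv")


class PipelineError(RuntimeError):
    """A stage is missing its upstream outputs."""


def _require(path: Path, stage: str, upstream: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"stage {stage!r}: missing upstream output {path.name} "
            f"(enable stage {upstream!r} or provide the file)"
        )
    return path


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages in order; returns the run directory."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = provenance_block(config.seed, config.raw)
    stages = config.stages

    subject_ids: list[str] = []
    if stages.get("simulate"):
        log.info("simulate: generating cohort (seed=%d)", config.seed)
        subjects, table = generate_cohort(config.cohort, seed=config.seed)
        for subject in subjects:
            save_subject(subject, outdir, provenance=prov)
        table.to_csv(outdir / "cohort.csv", index=False)
        subject_ids = [s.subject_id for s in subjects]
    else:
        subject_ids = sorted(
            p.name.replace("_truth.json", "")
            for p in outdir.glob("*_truth.json")
        )

    if not any(
        stages.get(s) for s in ("fit_t1", "segment_lge", "ecv", "segments", "report")
    ):
        return outdir

    cohort_path = _require(outdir / "cohort.csv", "fit_t1", "simulate")
    cohort = pd.read_csv(cohort_path)

    if stages.get("fit_t1"):
        for sid in subject_ids:
            try:
                subject = load_subject(outdir, sid)
                t1_maps, shifts = fit_subject_t1_maps(
                    subject, register=config.register
                )
                for label, tmap in t1_maps.items():
                    save_t1_map(
                        tmap,
                        outdir / f"{sid}_t1map_{label}.nii.gz",
                        subject.geometry.pixel_spacing,
                    )
                diag = {
                    "subject_id": sid,
                    "registration_shifts": {
                        k: np.asarray(v).tolist() for k, v in shifts.items()
                    },
                    "valid_fraction": {
                        label: float(t.validity_mask.mean())
                        for label, t in t1_maps.items()
                    },
                    "provenance": prov,
                }
                dump_json(diag, outdir / f"{sid}_t1fit.json")
            except Exception:
                log.exception("fit_t1 failed for %s; skipping subject", sid)

    if stages.get("segment_lge"):
        rows = []
        for sid in subject_ids:
            try:
                subject = load_subject(outdir, sid)
                if not subject.lge_positive:
                    continue
                image = LgeImage(subject.lge_image, subject.myocardium_mask)
                core = auto_core_roi(
                    subject.region_map, REGION_LABELS["lesion_core"]
                )
                mask = classify_enhancement(
                    image, locate_core_max_si(image, core)
                )
                import nibabel as nib

                nib.save(
                    nib.Nifti1Image(
                        mask.classes.astype(np.uint8), np.eye(4)
                    ),
                    str(outdir / f"{sid}_enhmask.nii.gz"),
                )
                for cls, count in mask.class_counts().items():
                    sel = mask.pixels_of(cls)
                    rows.append(
                        {
                            "subject_id": sid,
                            "class": cls,
                            "n_pixels": count,
                            "mean_si": float(subject.lge_image[sel].mean())
                            if count
                            else np.nan,
                            "max_si": mask.max_si,
                        }
                    )
            except Exception:
                log.exception("segment_lge failed for %s; skipping subject", sid)
        pd.DataFrame(rows).to_csv(outdir / "lge_classes.csv", index=False)

    results_rows = []
    if stages.get("ecv") or stages.get("segments"):
        segmental = bool(stages.get("segments"))
        for sid in subject_ids:
            try:
                subject = load_subject(outdir, sid)
                t1_maps = {}
                for label in MOLLI_SUFFIX:
                    path = _require(
                        outdir / f"{sid}_t1map_{label}.nii.gz", "ecv", "fit_t1"
                    )
                    t1_maps[label] = load_t1_map(path)
                result = analyze_subject(
                    subject,
                    register=config.register,
                    segmental=segmental,
                    t1_maps=t1_maps,
                )
                row = {
                    "subject_id": sid,
                    "group": subject.group_label,
                    "lge_positive": subject.lge_positive,
                    "hematocrit": subject.tissue.hematocrit,
                }
                if result.ecv_global is not None:
                    row["ecv"] = result.ecv_global.ecv
                    row["lambda"] = result.ecv_global.lambda_
                    row["r_squared"] = result.ecv_global.r_squared
                for cls, res in result.ecv_by_class.items():
                    row[f"ecv_{cls}"] = res.ecv
                for name, res in result.ecv_by_segment.items():
                    row[f"ecv_seg_{name}"] = res.ecv
                    row[f"wt_{name}"] = result.wall_thickness_mm[name]
                    row[f"hypertrophic_{name}"] = result.hypertrophic[name]
                if result.max_wall_thickness_mm is not None:
                    row["max_wall_thickness_mm"] = result.max_wall_thickness_mm
                if result.lv_mass_indexed is not None:
                    row["lv_mass_g"] = result.lv_mass_g
                    row["lv_mass_indexed"] = result.lv_mass_indexed
                results_rows.append(row)
                payload = {
                    "subject_id": sid,
                    "ecv": row.get("ecv"),
                    "by_class": {
                        c: vars(r) for c, r in result.ecv_by_class.items()
                    },
                    "by_segment": {
                        n: vars(r) for n, r in result.ecv_by_segment.items()
                    },
                    "provenance": prov,
                }
                dump_json(payload, outdir / f"{sid}_ecv.json")
            except PipelineError:
                raise
            except Exception:
                log.exception("ecv failed for %s; skipping subject", sid)
        results = cohort.merge(
            pd.DataFrame(results_rows).drop(
                columns=["group", "lge_positive", "hematocrit"]
            ),
            on="subject_id",
            how="left",
        )
        results.to_csv(outdir / "results.csv", index=False)

    if stages.get("report"):
        results_path = _require(outdir / "results.csv", "report", "ecv")
        _write_report(pd.read_csv(results_path), outdir, prov)
    return outdir


def _write_report(results: pd.DataFrame, outdir: Path, prov: dict) -> None:
    """Cohort-level summary tables and hypothesis tests."""
    tests: dict = {"provenance": prov}
    groups = results["group"].unique().tolist()
    rows = []
    for col in ("age", "bsa", "systolic_bp", "diastolic_bp", "hematocrit", "ecv"):
        if col not in results:
            continue
        row = {"variable": col}
        for g in groups:
            vals = results.loc[results["group"] == g, col].dropna()
            row[f"{g}_mean"] = vals.mean()
            row[f"{g}_sd"] = vals.std(ddof=1)
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "table1.csv", index=False)

    if {"HCM", "control"} <= set(groups):
        two = results[results["group"].isin(["HCM", "control"])]
        if (two.groupby("group")["ecv"].count() >= 2).all():
            res = compare_groups(two, "ecv", "group")
            tests["ecv_hcm_vs_control"] = {
                "t": res.statistic,
                "df": res.df,
                "p": res.p_value,
                "summaries": res.group_summaries,
            }
        sex_counts = pd.crosstab(two["group"], two["sex"])
        if sex_counts.shape == (2, 2) and (sex_counts.sum(0) > 0).all():
            res = proportion_test(sex_counts.to_numpy())
            tests["sex_proportion"] = {
                "chi2": res.statistic,
                "df": res.df,
                "p": res.p_value,
            }

    seg_cols = [c for c in results.columns if c.startswith("ecv_seg_")]
    if seg_cols:
        table2 = []
        for col in seg_cols:
            row = {"segment": col.replace("ecv_seg_", "")}
            for g in groups:
                vals = results.loc[results["group"] == g, col].dropna()
                row[f"{g}_mean"] = vals.mean()
                row[f"{g}_sd"] = vals.std(ddof=1)
            table2.append(row)
        pd.DataFrame(table2).to_csv(outdir / "table2.csv", index=False)
        long = results.melt(
            id_vars=["subject_id"], value_vars=seg_cols,
            var_name="segment", value_name="seg_ecv",
        ).dropna()
        if long["segment"].nunique() >= 3 and (
            long.groupby("segment")["seg_ecv"].count() >= 2
        ).all():
            res = anova_bonferroni(long, "seg_ecv", "segment")
            tests["segmental_anova"] = {
                "F": res.statistic,
                "p": res.p_value,
                "pairwise_p": {f"{a}|{b}": p for (a, b), p in res.pairwise_p.items()},
            }
    dump_json(tests, outdir / "tests.json")
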