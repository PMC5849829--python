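"""End-to-end orchestration of the registration validation workflow.

One subject runs as: (1) fiducial registration of the surrogate volume onto
the fixed volume with residual reporting; (2) fiducial-based rigid
registration of the moving volume onto the fixed geometry; (3) automatic
estimation of translation-only local alignments against the reference
volume and synthesis of the dense deformation field; (4) deformable
resampling; (5) Pearson and NMI scoring of rigid-vs-reference and
deformed-vs-reference inside every configured ROI.  A cohort run repeats
this per subject and assembles the report tables.

The reference volume for both alignment estimation and metric evaluation is
the surrogate (the same-geometry planning MRI), which keeps block matching
within one modality.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from . import evaluation_stats, similarity_metrics
from .evaluation_stats import SimilarityReport, build_report_tables
from .fiducial_registration import fit_point_rigid, residual_errors
from .image_model import (
    PointSet,
    RigidTransform,
    VolumetricImage,
    load_fiducials,
    load_image,
    load_mask,
    resample_deformable,
    resample_rigid,
)
from .local_rigid_dir import estimate_local_alignments, synthesize_dvf

__all__ = [
    "RunConfig",
    "SubjectData",
    "SubjectResult",
    "PipelineError",
    "run_subject",
    "run_subject_data",
    "run_cohort",
    "grid_seeds",
]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """File-based configuration of one subject run."""

    subject_id: str
    fixed: str                    # fixed volume (e.g. planning CT), NIfTI
    moving: str                   # moving volume (e.g. diagnostic MRI), NIfTI
    surrogate: str                # surrogate volume (e.g. planning MRI), NIfTI
    rois: dict                    # name -> mask NIfTI path
    fiducials_fixed: str          # CSV
    fiducials_moving: str         # CSV
    fiducials_surrogate: str      # CSV
    out_dir: str | None = None
    bins: int = 64
    nmi_variant: str = "excess"
    weight_floor: float = 1e-6
    block_radius_mm: float = 8.0
    block_search_mm: float = 10.0
    seed_grid: tuple = (4, 4, 4)

    def validate(self) -> None:
        paths = [self.fixed, self.moving, self.surrogate,
                 self.fiducials_fixed, self.fiducials_moving, self.fiducials_surrogate,
                 *self.rois.values()]
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")
        if self.bins < 2:
            raise ValueError("bins must be >= 2")
        if self.nmi_variant not in similarity_metrics.NMI_VARIANTS:
            raise ValueError(f"unknown NMI variant {self.nmi_variant!r}")


@dataclass
class SubjectData:
    """In-memory inputs of one subject run."""

    subject_id: str
    fixed: VolumetricImage
    moving: VolumetricImage
    surrogate: VolumetricImage
    rois: dict
    fiducials_fixed: PointSet
    fiducials_moving: PointSet
    fiducials_surrogate: PointSet


@dataclass
class SubjectResult:
    subject_id: str
    residual_report: object
    similarity_reports: list
    rigid_transform: RigidTransform
    dvf: object
    n_alignments: int
    rigid_image: VolumetricImage = None
    deformed_image: VolumetricImage = None


def grid_seeds(reference: VolumetricImage, mask, grid: tuple, margin_mm: float) -> PointSet:
    """Regular seed grid spanning the mask's bounding box, inset by `margin_mm`
    so every block-matching window stays inside the volume."""
    idx = np.argwhere(mask.voxels)
    lo = reference.voxel_to_physical(idx.min(axis=0).astype(float))
    hi = reference.voxel_to_physical(idx.max(axis=0).astype(float))
    lo, hi = np.minimum(lo, hi), np.maximum(lo, hi)
    vol_lo = reference.voxel_to_physical(np.zeros(3)) + margin_mm
    vol_hi = reference.voxel_to_physical(np.asarray(reference.shape) - 1.0) - margin_mm
    lo, hi = np.maximum(lo, vol_lo), np.minimum(hi, vol_hi)
    axes = [np.linspace(lo[k], hi[k], grid[k]) for k in range(3)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    return PointSet([f"seed_{i}" for i in range(len(pts))], pts)


def _checksum(arr) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:12]


def run_subject_data(
    data: SubjectData,
    bins: int = 64,
    nmi_variant: str = "excess",
    weight_floor: float = 1e-6,
    block_radius_mm: float = 8.0,
    block_search_mm: float = 10.0,
    seed_grid: tuple = (4, 4, 4),
    keep_images: bool = False,
) -> SubjectResult:
    """Run the full per-subject workflow on in-memory inputs."""
    sid = data.subject_id
    log.info("[%s] fixed volume checksum %s", sid, _checksum(data.fixed.voxels))

    # -- surrogate -> fixed fiducial registration (quality gate) ----------
    try:
        t_surr = fit_point_rigid(data.fiducials_surrogate, data.fiducials_fixed)
        residuals = residual_errors(t_surr, data.fiducials_surrogate,
                                    data.fiducials_fixed, subject_id=sid)
    except Exception as e:  # noqa: BLE001 - stage attribution
        raise PipelineError("register-fiducials", str(e)) from e
    log.info("[%s] surrogate fiducial residual mean %.3f mm", sid, residuals.mean_mm)

    # -- rigid moving -> fixed via fiducials ------------------------------
    try:
        t_rigid = fit_point_rigid(data.fiducials_moving, data.fiducials_fixed)
        rigid_img = resample_rigid(data.moving, data.fixed, t_rigid.inverse())
    except Exception as e:  # noqa: BLE001
        raise PipelineError("rigid-registration", str(e)) from e

    # -- local alignments + DVF synthesis ---------------------------------
    try:
        eval_roi = data.rois.get("expanded") or next(iter(data.rois.values()))
        seeds = grid_seeds(data.fixed, eval_roi, seed_grid,
                           margin_mm=block_radius_mm + block_search_mm)
        alignments = estimate_local_alignments(
            data.surrogate, rigid_img, seeds,
            radius_mm=block_radius_mm, search_mm=block_search_mm,
        )
        if not alignments:
            raise ValueError("no usable local alignments were estimated")
        dvf = synthesize_dvf(alignments, RigidTransform.identity(),
                             data.fixed, weight_floor=weight_floor)
        deformed_img = resample_deformable(rigid_img, data.fixed, dvf)
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("synthesize-dvf", str(e)) from e
    log.info("[%s] %d local alignments used", sid, len(alignments))

    # -- evaluation against the surrogate ----------------------------------
    try:
        reports = []
        for roi_name, mask in data.rois.items():
            for metric, fn in (
                ("nmi", lambda x, m: similarity_metrics.nmi_in_roi(
                    data.surrogate, x, m, bins=bins, variant=nmi_variant)),
                ("pearson", lambda x, m: similarity_metrics.pearson_in_roi(
                    data.surrogate, x, m)),
            ):
                reports.append(SimilarityReport(
                    sid, roi_name, metric,
                    rigid_value=fn(rigid_img, mask),
                    deform_value=fn(deformed_img, mask),
                ))
    except Exception as e:  # noqa: BLE001
        raise PipelineError("evaluate", str(e)) from e

    return SubjectResult(
        sid, residuals, reports, t_rigid, dvf, len(alignments),
        rigid_image=rigid_img if keep_images else None,
        deformed_image=deformed_img if keep_images else None,
    )


def run_subject(config: RunConfig) -> SubjectResult:
    """File-based variant of :func:`run_subject_data`."""
    missing_fid = [p for p in (config.fiducials_fixed, config.fiducials_moving,
                               config.fiducials_surrogate) if not Path(p).exists()]
    if missing_fid:
        raise PipelineError("register-fiducials",
                            f"missing fiducial files: {missing_fid}")
    try:
        config.validate()
        data = SubjectData(
            subject_id=config.subject_id,
            fixed=load_image(config.fixed),
            moving=load_image(config.moving),
            surrogate=load_image(config.surrogate),
            rois={name: load_mask(p, name) for name, p in config.rois.items()},
            fiducials_fixed=load_fiducials(config.fiducials_fixed),
            fiducials_moving=load_fiducials(config.fiducials_moving),
            fiducials_surrogate=load_fiducials(config.fiducials_surrogate),
        )
    except (FileNotFoundError, ValueError) as e:
        raise PipelineError("load-inputs", str(e)) from e
    result = run_subject_data(
        data, bins=config.bins, nmi_variant=config.nmi_variant,
        weight_floor=config.weight_floor, block_radius_mm=config.block_radius_mm,
        block_search_mm=config.block_search_mm, seed_grid=config.seed_grid,
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = [
            {"subject_id": r.subject_id, "roi": r.roi_name, "metric": r.metric_name,
             "rigid": r.rigid_value, "deform": r.deform_value, "pct_change": r.pct_change}
            for r in result.similarity_reports
        ]
        (out / f"{config.subject_id}_metrics.json").write_text(json.dumps(rows, indent=2))
    return result


def run_cohort(subjects: list, out_dir=None, **kwargs) -> dict:
    """Run every subject (``RunConfig`` or ``SubjectData``), then the cohort
    statistics.  Per-subject failures are collected into a failure manifest;
    the cohort proceeds with the survivors."""
    ids = [s.subject_id for s in subjects]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate subject ids: {dupes}")
    if not subjects:
        raise ValueError("cohort needs >= 1 subject")

    results, failures = [], {}
    for s in subjects:
        try:
            if isinstance(s, RunConfig):
                results.append(run_subject(s))
            else:
                results.append(run_subject_data(s, **kwargs))
        except PipelineError as e:
            log.error("[%s] %s", s.subject_id, e)
            failures[s.subject_id] = {"stage": e.stage, "error": str(e)}

    sim = [r for res in results for r in res.similarity_reports]
    residual_reports = [res.residual_report for res in results]
    t1, t2 = build_report_tables(residual_reports, sim, out_dir=out_dir)

    summary = {}
    for (roi, metric), grp in _grouped(sim):
        mean_pct, pct_of_means = evaluation_stats.cohort_metric_summary(grp)
        entry = {
            "n": len(grp),
            "improved": evaluation_stats.improvement_count(grp),
            "mean_pct_change": mean_pct,
            "pct_change_of_means": pct_of_means,
        }
        if len(grp) >= 2:
            t = evaluation_stats.paired_t_test(
                [g.rigid_value for g in grp], [g.deform_value for g in grp])
            entry["paired_t"] = t.t
            entry["paired_p"] = t.p_two_sided
        summary[f"{roi}/{metric}"] = entry

    if out_dir is not None and failures:
        Path(out_dir, "failures.json").write_text(json.dumps(failures, indent=2))
    return {"results": results, "failures": failures,
            "table1": t1, "table2": t2, "summary": summary}


def subject_data_from_phantom(subject, roi_names=("expanded",)) -> SubjectData:
    """Adapt a synthetic :class:`~regsurrogate.phantom.PhantomSubject` to the
    pipeline's input bundle.

    The planning CT is the fixed volume, the diagnostic MRI the moving
    volume, the planning MRI the surrogate; planning-space fiducial
    positions serve for both the fixed and surrogate sets, the transported
    positions for the moving set.
    """
    return SubjectData(
        subject_id=f"phantom-{subject.spec.seed}",
        fixed=subject.planning_ct,
        moving=subject.diagnostic_mri,
        surrogate=subject.planning_mri,
        rois={n: subject.masks[n] for n in roi_names},
        fiducials_fixed=subject.fiducials_planning,
        fiducials_moving=subject.fiducials_diagnostic,
        fiducials_surrogate=subject.fiducials_planning,
    )


def _grouped(reports):
    keys = sorted({(r.roi_name, r.metric_name) for r in reports})
    for key in keys:
        yield key, [r for r in reports if (r.roi_name, r.metric_name) == key]
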