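"""Cohort-level statistics and report tables for the registration study.

Paired Student's t-tests, improvement counts, cohort percent-change
aggregations, covariate correlations, and the two tabular reports: the
fiducial-residual table (per-subject rows, cohort mean/SD footer) and the
rigid-vs-deformable similarity table (per-subject metric rows, footer with
both cohort aggregations, improvement counts and the paired-t p-value).

Because "average percent improvement" is ambiguous — the mean of per-subject
percent changes and the percent change of the cohort means generally differ —
both aggregations are always reported side by side.
"""

from __future__ import annotations

import logging
from collections import namedtuple
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .similarity_metrics import percent_change

__all__ = [
    "SimilarityReport",
    "PairedTResult",
    "paired_t_test",
    "improvement_count",
    "cohort_metric_summary",
    "covariate_correlation",
    "build_report_tables",
]

log = logging.getLogger(__name__)

PairedTResult = namedtuple("PairedTResult", ["t", "dof", "p_two_sided", "degenerate"])


@dataclass
class SimilarityReport:
    """One (subject, ROI, metric) row: rigid vs deformable value and % change."""

    subject_id: str
    roi_name: str
    metric_name: str
    rigid_value: float
    deform_value: float
    pct_change: float = None

    def __post_init__(self):
        computed = percent_change(self.rigid_value, self.deform_value)
        if self.pct_change is None:
            self.pct_change = computed
        elif abs(self.pct_change - computed) > 0.005:
            raise ValueError(
                f"{self.subject_id}/{self.roi_name}/{self.metric_name}: stated "
                f"pct_change {self.pct_change} inconsistent with values ({computed:.4f})"
            )


def paired_t_test(x, y) -> PairedTResult:
    """Two-sided paired Student's t-test on differences d = y - x.

    t = mean(d) / (sd(d)/sqrt(n)) with the sample (n-1) SD; dof = n-1.
    Zero-variance differences are degenerate: p = 1 when the common
    difference is 0, else p = 0 (flagged, not raised).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = len(x)
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    d = y - x
    sd = d.std(ddof=1)
    dof = n - 1
    if sd == 0:
        if d.mean() == 0:
            return PairedTResult(0.0, dof, 1.0, True)
        t = np.inf if d.mean() > 0 else -np.inf
        return PairedTResult(t, dof, 0.0, True)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), dof)
    return PairedTResult(float(t), dof, float(p), False)


def improvement_count(reports: list) -> int:
    """Number of subjects whose deformable score improved (pct_change > 0).

    Expects one report per subject for a fixed (ROI, metric); a tie at
    exactly 0 does not count as improvement.
    """
    ids = [r.subject_id for r in reports]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate subjects: {dupes}")
    return sum(1 for r in reports if r.pct_change > 0)


def cohort_metric_summary(reports: list) -> tuple:
    """Both cohort aggregations of percent change, side by side.

    Returns ``(mean_pct_change, pct_change_of_means)``: (a) the arithmetic
    mean of per-subject percent changes; (b) the percent change computed
    from the cohort means of the rigid and deformable values.
    """
    if not reports:
        raise ValueError("cohort summary needs >= 1 report")
    mean_pct = float(np.mean([r.pct_change for r in reports]))
    mean_rigid = float(np.mean([r.rigid_value for r in reports]))
    mean_deform = float(np.mean([r.deform_value for r in reports]))
    return mean_pct, percent_change(mean_rigid, mean_deform)


def covariate_correlation(volume_changes, metric_values) -> tuple:
    """Pearson r (and two-sided p) of |organ volume change| vs metric value."""
    v = np.abs(np.asarray(volume_changes, dtype=float))
    m = np.asarray(metric_values, dtype=float)
    if v.shape != m.shape or len(v) < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if v.std() == 0 or m.std() == 0:
        raise ValueError("correlation undefined: zero variance")
    r, p = stats.pearsonr(v, m)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def _residual_table(residual_reports: list) -> pd.DataFrame:
    labels = sorted({lab for r in residual_reports for lab, _ in r.per_point})
    rows = []
    for r in residual_reports:
        row = {"subject_id": r.subject_id}
        d = dict(r.per_point)
        for lab in labels:
            row[f"residual_{lab}_mm"] = round(d[lab], 2) if lab in d else np.nan
        row["mean_mm"] = round(r.mean_mm, 2)
        rows.append(row)
    df = pd.DataFrame(rows)
    pooled = np.concatenate([r.distances for r in residual_reports]) if residual_reports else np.array([])
    footer = {"subject_id": "All fiducials (mean/sd)"}
    if pooled.size:
        footer["mean_mm"] = round(float(pooled.mean()), 2)
        footer["sd_mm"] = round(float(pooled.std(ddof=1)), 2) if pooled.size > 1 else np.nan
    return pd.concat([df, pd.DataFrame([footer])], ignore_index=True)


def _similarity_table(similarity_reports: list) -> pd.DataFrame:
    rows = [
        {
            "subject_id": r.subject_id,
            "roi": r.roi_name,
            "metric": r.metric_name,
            "rigid": round(r.rigid_value, 3),
            "deform": round(r.deform_value, 3),
            "pct_change": round(r.pct_change, 2),
        }
        for r in similarity_reports
    ]
    df = pd.DataFrame(
        rows, columns=["subject_id", "roi", "metric", "rigid", "deform", "pct_change"]
    )
    footers = []
    for (roi, metric), grp in _group_reports(similarity_reports):
        mean_pct, pct_of_means = cohort_metric_summary(grp)
        res = paired_t_test([g.rigid_value for g in grp], [g.deform_value for g in grp]) \
            if len(grp) >= 2 else None
        footers.append(
            {
                "subject_id": "COHORT",
                "roi": roi,
                "metric": metric,
                "rigid": round(float(np.mean([g.rigid_value for g in grp])), 3),
                "deform": round(float(np.mean([g.deform_value for g in grp])), 3),
                "pct_change": round(mean_pct, 2),
                "pct_change_of_means": round(pct_of_means, 2),
                "improved_of_n": f"{improvement_count(grp)}/{len(grp)}",
                "paired_t_p": round(res.p_two_sided, 6) if res else np.nan,
            }
        )
    return pd.concat([df, pd.DataFrame(footers)], ignore_index=True)


def _group_reports(reports):
    keys = sorted({(r.roi_name, r.metric_name) for r in reports})
    for key in keys:
        yield key, [r for r in reports if (r.roi_name, r.metric_name) == key]


def build_report_tables(
    residual_reports: list,
    similarity_reports: list,
    subject_metadata: pd.DataFrame | None = None,
    out_dir=None,
) -> tuple:
    """Assemble the residual and similarity report tables.

    Subjects present in one input but missing from the other are listed in a
    logged warning, never dropped silently.  When `out_dir` is given the
    tables are written as ``table1_residuals.csv`` and
    ``table2_similarity.csv``.
    """
    res_ids = {r.subject_id for r in residual_reports}
    sim_ids = {r.subject_id for r in similarity_reports}
    if residual_reports and similarity_reports and res_ids != sim_ids:
        log.warning(
            "subjects missing from one input: residual-only %s, similarity-only %s",
            sorted(res_ids - sim_ids), sorted(sim_ids - res_ids),
        )
    t1 = _residual_table(residual_reports) if residual_reports else pd.DataFrame(
        columns=["subject_id", "mean_mm", "sd_mm"]
    )
    t2 = _similarity_table(similarity_reports)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        t1.to_csv(out / "table1_residuals.csv", index=False)
        t2.to_csv(out / "table2_similarity.csv", index=False)
    return t1, t2
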