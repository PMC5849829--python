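"""Point-based rigid registration of fiducial marker sets.

Closed-form least-squares (Kabsch/Umeyama) alignment of label-matched point
pairs, per-point residual reporting, and cohort residual summaries.  Points
are matched by label, never by proximity; a fiducial that could not be
localized is simply absent from the set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_model import PointSet, RigidTransform

__all__ = [
    "ResidualReport",
    "DegenerateConfigurationError",
    "fit_point_rigid",
    "residual_errors",
    "cohort_residual_summary",
]


class DegenerateConfigurationError(ValueError):
    """Fewer than 3 point pairs, or a collinear configuration."""


@dataclass
class ResidualReport:
    """Per-fiducial post-registration distances (mm) for one subject."""

    subject_id: str
    per_point: list  # [(label, distance_mm), ...]

    @property
    def distances(self) -> np.ndarray:
        return np.array([d for _, d in self.per_point], dtype=float)

    @property
    def mean_mm(self) -> float:
        return float(self.distances.mean())


def _matched(moving: PointSet, fixed: PointSet):
    mset, fset = set(moving.labels), set(fixed.labels)
    if mset != fset:
        only_m = sorted(mset - fset)
        only_f = sorted(fset - mset)
        raise ValueError(
            f"unmatched fiducial labels: moving-only {only_m}, fixed-only {only_f}"
        )
    labels = list(moving.labels)  # preserve moving order
    m = moving.positions
    f = np.array([fixed.position_of(l) for l in labels])
    return labels, m, f


def fit_point_rigid(moving: PointSet, fixed: PointSet) -> RigidTransform:
    """Least-squares rigid transform T minimizing sum ||T(m_i) - f_i||^2.

    Closed form: centroid subtraction, cross-covariance, SVD, with the
    determinant-sign correction that forces a proper rotation (no scaling,
    no reflection).  Requires >= 3 label-matched, non-collinear pairs.
    """
    _, m, f = _matched(moving, fixed)
    n = len(m)
    if n < 3:
        raise DegenerateConfigurationError(f"need >= 3 matched points, got {n}")
    mc = m - m.mean(axis=0)
    fc = f - f.mean(axis=0)
    # collinearity: rank of the centered configuration < 2
    if np.linalg.matrix_rank(mc, tol=1e-9 * max(1.0, np.abs(mc).max())) < 2:
        raise DegenerateConfigurationError("points are collinear (or coincident)")
    h = mc.T @ fc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = f.mean(axis=0) - rot @ m.mean(axis=0)
    return RigidTransform(rot, t)


def residual_errors(
    transform: RigidTransform, moving: PointSet, fixed: PointSet, subject_id: str = ""
) -> ResidualReport:
    """Per-point Euclidean distances ||T(m_i) - f_i|| and their mean."""
    labels, m, f = _matched(moving, fixed)
    dist = np.linalg.norm(transform.apply(m) - f, axis=1)
    return ResidualReport(subject_id, list(zip(labels, dist.tolist())))


def cohort_residual_summary(reports: list) -> tuple:
    """Pooled (mean, sample SD) over ALL per-fiducial residuals across subjects.

    The sample standard deviation uses the n-1 denominator.
    """
    if len(reports) < 2:
        raise ValueError("cohort summary needs >= 2 subject reports")
    pooled = np.concatenate([r.distances for r in reports])
    return float(pooled.mean()), float(pooled.std(ddof=1))
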