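"""Deformable registration synthesized from local rigid alignments.

The deformation model: a set of rigid transforms, each anchored at a spatial
center and carrying a Gaussian influence scale, is blended into a dense
deformation vector field.  At each fixed-space voxel the displacement is the
Gaussian-weighted (normalized) mean of the displacements implied by every
local alignment; far from all alignments the field falls back to a global
rigid displacement.  No image similarity metric enters the synthesis — the
local alignments fully determine the field.

Also provided: a Jacobian-determinant diagnostic and an automatic
block-matching estimator of translation-only local alignments, so the
pipeline can run without a human operator placing alignments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .image_model import (
    DeformationField,
    PointSet,
    RigidTransform,
    VolumetricImage,
)

__all__ = [
    "LocalAlignment",
    "implied_vector",
    "gaussian_weight",
    "default_sigma_mm",
    "synthesize_dvf",
    "jacobian_determinant_map",
    "estimate_local_alignments",
]

log = logging.getLogger(__name__)


@dataclass
class LocalAlignment:
    """A rigid transform valid near `center`, blended with Gaussian weight.

    `transform` maps fixed physical coordinates to moving physical
    coordinates; `sigma_mm` is the Gaussian influence scale.
    """

    center: np.ndarray
    transform: RigidTransform
    sigma_mm: float

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.sigma_mm = float(self.sigma_mm)
        if self.sigma_mm <= 0:
            raise ValueError("sigma_mm must be > 0")


def implied_vector(alignment: LocalAlignment, x) -> np.ndarray:
    """Displacement v(x) = T(x) - x taking a fixed-space location to its
    moving-space sample point."""
    x = np.asarray(x, dtype=float)
    return alignment.transform.apply(x) - x


def gaussian_weight(alignment: LocalAlignment, x) -> np.ndarray:
    """w(x) = exp(-||x - center||^2 / (2 sigma^2))."""
    x = np.asarray(x, dtype=float)
    d2 = np.sum((x - alignment.center) ** 2, axis=-1)
    return np.exp(-d2 / (2.0 * alignment.sigma_mm**2))


def default_sigma_mm(centers: np.ndarray) -> float:
    """Median nearest-neighbor distance among alignment centers.

    Adapts the mixing smoothness to alignment density; falls back to 10 mm
    for a single center.
    """
    centers = np.asarray(centers, dtype=float).reshape(-1, 3)
    if len(centers) < 2:
        return 10.0
    d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return float(np.median(d.min(axis=1)))


def synthesize_dvf(
    alignments: list,
    fallback: RigidTransform,
    fixed_geometry: VolumetricImage,
    weight_floor: float = 1e-6,
) -> DeformationField:
    """Blend local rigid alignments into a dense pull-back deformation field.

    At each voxel center x:
        d(x) = sum_i w_i(x) v_i(x) / sum_i w_i(x)    if sum_i w_i(x) >= floor
        d(x) = fallback(x) - x                        otherwise

    The normalized weighted mean (rather than a raw weighted sum) makes the
    field degenerate exactly to a rigid displacement field when every
    alignment carries the same transform.
    """
    if not alignments:
        raise ValueError("synthesize_dvf needs at least one local alignment")
    if weight_floor <= 0:
        raise ValueError("weight_floor must be > 0")
    x = fixed_geometry.physical_grid()  # (*shape, 3)
    flat = x.reshape(-1, 3)
    wsum = np.zeros(flat.shape[0])
    vsum = np.zeros_like(flat)
    for a in alignments:
        w = gaussian_weight(a, flat)
        vsum += w[:, None] * implied_vector(a, flat)
        wsum += w
    covered = wsum >= weight_floor
    d = np.empty_like(flat)
    d[covered] = vsum[covered] / wsum[covered, None]
    if not covered.all():
        d[~covered] = fallback.apply(flat[~covered]) - flat[~covered]
    return DeformationField(
        d.reshape(x.shape), fixed_geometry.spacing.copy(),
        fixed_geometry.origin.copy(), fixed_geometry.orientation.copy()
    )


def jacobian_determinant_map(dvf: DeformationField) -> VolumetricImage:
    """det(I + grad d) per voxel — central differences in the interior,
    one-sided at the borders.  Values <= 0 flag local folding."""
    if min(dvf.shape) < 2:
        raise ValueError("Jacobian map needs >= 2 voxels per axis")
    # displacement is a function of physical position; on an oriented grid the
    # index-axis derivative equals the directional derivative along that
    # column of the orientation matrix scaled by spacing.
    grads = [
        np.stack(np.gradient(dvf.displacement[..., c], *dvf.spacing, axis=(0, 1, 2)), axis=-1)
        for c in range(3)
    ]
    j = np.stack(grads, axis=-2)  # (*shape, 3 component, 3 index-axis)
    # convert index-axis derivatives to physical-axis derivatives: J_phys = J_idx @ R^T
    j = j @ dvf.orientation.T
    det = np.linalg.det(np.eye(3) + j)
    out = VolumetricImage(det, dvf.spacing.copy(), dvf.origin.copy(), dvf.orientation.copy())
    return out


def _sphere_offsets(radius_mm: float, spacing: np.ndarray) -> np.ndarray:
    r_vox = np.maximum(1, np.floor(radius_mm / spacing).astype(int))
    axes = [np.arange(-r, r + 1) for r in r_vox]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    keep = np.linalg.norm(grid * spacing, axis=1) <= radius_mm
    return grid[keep]


def estimate_local_alignments(
    fixed: VolumetricImage,
    moving: VolumetricImage,
    seeds: PointSet,
    radius_mm: float = 8.0,
    search_mm: float = 10.0,
    min_correlation: float = 0.5,
    tie_tolerance: float = 0.01,
) -> list:
    """Block-matching estimator of translation-only local alignments.

    For each seed point, the spherical patch of `radius_mm` around it in the
    fixed image is compared against translated patches of the moving image on
    an exhaustive voxel-grid search within +/- `search_mm` per axis; the
    translation maximizing Pearson correlation wins.  ``sigma_mm`` of each
    returned alignment is set to `radius_mm`.

    Two safeguards reject noise-driven matches: a seed whose best correlation
    falls below `min_correlation` is treated as structureless and skipped
    (the patch is matching noise, not anatomy), and among candidates within
    `tie_tolerance` of the best correlation the smallest translation is
    preferred, so statistically indistinguishable peaks cannot pull the
    field away from the identity.  Patches with zero intensity variance, or
    seeds whose search window leaves the volume, are likewise skipped with a
    logged warning.
    """
    if radius_mm <= 0 or search_mm <= 0:
        raise ValueError("radius_mm and search_mm must be > 0")
    if not fixed.same_geometry(moving):
        raise ValueError("block matching expects fixed and moving on one geometry")
    spacing = fixed.spacing
    patch = _sphere_offsets(radius_mm, spacing)  # (N, 3) int offsets
    s_vox = np.maximum(1, np.floor(search_mm / spacing).astype(int))
    search = np.stack(
        np.meshgrid(*[np.arange(-s, s + 1) for s in s_vox], indexing="ij"), axis=-1
    ).reshape(-1, 3)  # (S, 3)
    shape = np.asarray(fixed.shape)

    out = []
    for label, pos in zip(seeds.labels, seeds.positions):
        center = np.rint(fixed.physical_to_voxel(pos)).astype(int)
        lo = center + patch.min(axis=0) + search.min(axis=0)
        hi = center + patch.max(axis=0) + search.max(axis=0)
        if np.any(lo < 0) or np.any(hi >= shape):
            log.warning("seed %s: search window leaves the volume, skipped", label)
            continue
        pidx = center + patch  # (N, 3)
        fvals = fixed.voxels[pidx[:, 0], pidx[:, 1], pidx[:, 2]]
        fstd = fvals.std()
        if fstd == 0:
            log.warning("seed %s: fixed patch has zero variance, skipped", label)
            continue
        fnorm = (fvals - fvals.mean()) / fstd
        # gather all candidate moving patches in one fancy index: (S, N)
        cand = pidx[None, :, :] + search[:, None, :]
        mvals = moving.voxels[cand[..., 0], cand[..., 1], cand[..., 2]]
        mstd = mvals.std(axis=1)
        ok = mstd > 0
        if not ok.any():
            log.warning("seed %s: all moving patches have zero variance, skipped", label)
            continue
        mnorm = (mvals[ok] - mvals[ok].mean(axis=1, keepdims=True)) / mstd[ok, None]
        corr = mnorm @ fnorm / len(fnorm)
        if corr.max() < min_correlation:
            log.warning("seed %s: best correlation %.3f below %.3f, skipped",
                        label, corr.max(), min_correlation)
            continue
        near = corr >= corr.max() - tie_tolerance
        cands = search[ok][near]
        shift_mm = np.linalg.norm(cands * spacing, axis=1)
        best = cands[int(np.argmin(shift_mm))]
        t = fixed.voxel_to_physical(center + best) - fixed.voxel_to_physical(center)
        out.append(LocalAlignment(pos.copy(), RigidTransform.translation_only(t), radius_mm))
    return out
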