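"""Core geometric data model: images, masks, point sets, rigid transforms and
deformation fields, plus resampling and ROI algebra.

Conventions
-----------
* Physical coordinates are millimetres in the LPS axis convention.
* Voxel indices are 0-based; the image ``origin`` is the physical position of
  the **center** of voxel ``(0, 0, 0)``.
* Deformation fields use the pull-back convention: the field stores, for each
  fixed-space voxel at physical position ``x``, the offset ``d(x)`` such that
  the deformed image samples the moving image at ``x + d(x)``.
* NIfTI files carry RAS+ affines; they are converted to/from LPS on I/O.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "VolumetricImage",
    "ROIMask",
    "PointSet",
    "RigidTransform",
    "DeformationField",
    "GeometryError",
    "trilinear_sample",
    "resample_rigid",
    "resample_deformable",
    "combine_masks",
    "expand_mask",
    "load_image",
    "save_image",
    "load_mask",
    "save_mask",
    "load_dvf",
    "save_dvf",
    "load_fiducials",
    "save_fiducials",
]

_ORTHO_TOL = 1e-8


class GeometryError(ValueError):
    """Raised when image/mask/field geometries are inconsistent or invalid."""


def _as_vec3(v, name: str) -> np.ndarray:
    a = np.asarray(v, dtype=float).reshape(3)
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} must be finite, got {a}")
    return a


@dataclass
class VolumetricImage:
    """3D scalar grid with physical geometry.

    Parameters
    ----------
    voxels : (nx, ny, nz) float array
        Intensities in modality-dependent units.
    spacing : length-3, mm per voxel along each index axis.
    origin : length-3, mm; physical position of the center of voxel (0,0,0).
    orientation : 3x3 direction-cosine matrix (columns = index axes in LPS).
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise GeometryError(f"voxels must be 3-D, got shape {self.voxels.shape}")
        self.spacing = _as_vec3(self.spacing, "spacing")
        if np.any(self.spacing <= 0):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")
        self.origin = _as_vec3(self.origin, "origin")
        self.orientation = np.asarray(self.orientation, dtype=float).reshape(3, 3)
        if np.linalg.norm(self.orientation.T @ self.orientation - np.eye(3)) >= _ORTHO_TOL:
            raise GeometryError("orientation matrix is not orthonormal")

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    def geometry_like(self) -> "VolumetricImage":
        """Zero-filled image sharing this geometry (useful as a target grid)."""
        return VolumetricImage(
            np.zeros(self.shape), self.spacing.copy(), self.origin.copy(), self.orientation.copy()
        )

    def same_geometry(self, other, atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.orientation, other.orientation, atol=atol)
        )

    # -- voxel <-> physical ------------------------------------------------
    def voxel_to_physical(self, index) -> np.ndarray:
        """Map continuous voxel indices (..., 3) to physical mm (..., 3)."""
        idx = np.asarray(index, dtype=float)
        return self.origin + (idx * self.spacing) @ self.orientation.T

    def physical_to_voxel(self, point) -> np.ndarray:
        """Map physical mm coordinates (..., 3) to continuous voxel indices."""
        p = np.asarray(point, dtype=float)
        return ((p - self.origin) @ self.orientation) / self.spacing

    def physical_grid(self) -> np.ndarray:
        """Physical coordinates of every voxel center, shape (*shape, 3)."""
        idx = np.stack(
            np.meshgrid(*[np.arange(n, dtype=float) for n in self.shape], indexing="ij"),
            axis=-1,
        )
        return self.voxel_to_physical(idx)


@dataclass
class ROIMask:
    """Binary region-of-interest mask on the geometry of a reference image."""

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))
    name: str = ""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if not np.isin(self.voxels, (0, 1)).all():
            raise GeometryError(f"mask {self.name!r} has values outside {{0,1}}")
        self.voxels = self.voxels.astype(bool)
        self.spacing = _as_vec3(self.spacing, "spacing")
        self.origin = _as_vec3(self.origin, "origin")
        self.orientation = np.asarray(self.orientation, dtype=float).reshape(3, 3)

    @classmethod
    def from_image(cls, ref: VolumetricImage, voxels, name: str = "") -> "ROIMask":
        return cls(voxels, ref.spacing.copy(), ref.origin.copy(), ref.orientation.copy(), name)

    @property
    def shape(self):
        return self.voxels.shape

    def same_geometry(self, other, atol: float = 1e-9) -> bool:
        return VolumetricImage.same_geometry(self, other, atol)

    def voxel_count(self) -> int:
        return int(self.voxels.sum())

    def volume_ml(self) -> float:
        """Physical mask volume in millilitres."""
        return self.voxel_count() * float(np.prod(self.spacing)) / 1000.0


@dataclass
class PointSet:
    """Ordered labelled points in physical space (mm)."""

    labels: list
    positions: np.ndarray

    def __post_init__(self):
        self.labels = [str(l) for l in self.labels]
        self.positions = np.asarray(self.positions, dtype=float).reshape(len(self.labels), 3)
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise ValueError(f"duplicate point labels: {dupes}")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("point positions must be finite")

    def __len__(self) -> int:
        return len(self.labels)

    def position_of(self, label: str) -> np.ndarray:
        return self.positions[self.labels.index(label)]


@dataclass
class RigidTransform:
    """Proper rigid motion ``x -> R x + t`` between physical spaces (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = _as_vec3(self.translation, "translation")
        if np.linalg.norm(self.rotation.T @ self.rotation - np.eye(3)) >= _ORTHO_TOL:
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation has negative determinant (reflection)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def translation_only(cls, t) -> "RigidTransform":
        return cls(np.eye(3), t)

    def apply(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rinv = self.rotation.T
        return RigidTransform(rinv, -rinv @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply `other` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m) -> "RigidTransform":
        m = np.asarray(m, dtype=float).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])


@dataclass
class DeformationField:
    """Dense per-voxel displacement vectors (mm) on a fixed-image geometry,
    pull-back convention."""

    displacement: np.ndarray  # (*shape, 3)
    spacing: np.ndarray
    origin: np.ndarray
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.displacement.ndim != 4 or self.displacement.shape[-1] != 3:
            raise GeometryError(
                f"displacement must have shape (*grid, 3), got {self.displacement.shape}"
            )
        if not np.all(np.isfinite(self.displacement)):
            raise GeometryError("displacement components must be finite")
        self.spacing = _as_vec3(self.spacing, "spacing")
        self.origin = _as_vec3(self.origin, "origin")
        self.orientation = np.asarray(self.orientation, dtype=float).reshape(3, 3)

    @property
    def shape(self):
        return self.displacement.shape[:3]

    def same_geometry(self, other, atol: float = 1e-9) -> bool:
        return VolumetricImage.same_geometry(self, other, atol)

    def sample(self, points) -> np.ndarray:
        """Trilinearly interpolate the displacement at physical points (..., 3)."""
        ref = VolumetricImage(
            np.zeros(self.shape), self.spacing, self.origin, self.orientation
        )
        idx = ref.physical_to_voxel(points)
        flat = idx.reshape(-1, 3).T
        out = np.empty((flat.shape[1], 3))
        for c in range(3):
            out[:, c] = ndimage.map_coordinates(
                self.displacement[..., c], flat, order=1, mode="nearest"
            )
        return out.reshape(np.asarray(points, dtype=float).shape)


# ---------------------------------------------------------------------------
# Sampling and resampling
# ---------------------------------------------------------------------------

def trilinear_sample(image: VolumetricImage, points, fill: float = 0.0) -> np.ndarray:
    """Trilinear interpolation of `image` at physical `points` (..., 3).

    Points outside the voxel-center bounding box return `fill` exactly
    (no blending with interior values).
    """
    pts = np.asarray(points, dtype=float)
    scalar = pts.ndim == 1
    idx = image.physical_to_voxel(pts).reshape(-1, 3)
    hi = np.asarray(image.shape, dtype=float) - 1.0
    inside = np.all((idx >= 0) & (idx <= hi), axis=1)
    vals = np.full(idx.shape[0], float(fill))
    if inside.any():
        vals[inside] = ndimage.map_coordinates(
            image.voxels, idx[inside].T, order=1, mode="nearest"
        )
    if scalar:
        return float(vals[0])
    return vals.reshape(pts.shape[:-1])


def resample_rigid(
    moving: VolumetricImage,
    fixed_geometry: VolumetricImage,
    transform: RigidTransform,
    fill: float | None = None,
) -> VolumetricImage:
    """Resample `moving` onto `fixed_geometry` through a rigid map.

    `transform` maps fixed physical coordinates into moving physical
    coordinates (the inverse of a moving-to-fixed registration transform).
    `fill` defaults to the moving image's minimum.
    """
    if fill is None:
        fill = float(moving.voxels.min())
    x = fixed_geometry.physical_grid()
    vals = trilinear_sample(moving, transform.apply(x), fill)
    out = fixed_geometry.geometry_like()
    out.voxels = vals
    return out


def resample_deformable(
    moving: VolumetricImage,
    fixed_geometry: VolumetricImage,
    dvf: DeformationField,
    fill: float | None = None,
) -> VolumetricImage:
    """Resample `moving` onto `fixed_geometry` through a pull-back field:
    the output voxel at physical x holds ``moving(x + d(x))``."""
    if not dvf.same_geometry(fixed_geometry):
        raise GeometryError("deformation field geometry differs from the fixed geometry")
    if fill is None:
        fill = float(moving.voxels.min())
    x = fixed_geometry.physical_grid()
    vals = trilinear_sample(moving, x + dvf.displacement, fill)
    out = fixed_geometry.geometry_like()
    out.voxels = vals
    return out


# ---------------------------------------------------------------------------
# ROI algebra
# ---------------------------------------------------------------------------

def combine_masks(masks: list) -> ROIMask:
    """Voxelwise union of masks sharing one geometry ("combined structure")."""
    if not masks:
        raise ValueError("combine_masks needs at least one mask")
    first = masks[0]
    out = np.zeros(first.shape, dtype=bool)
    for m in masks:
        if not first.same_geometry(m):
            raise GeometryError(
                f"mask {m.name!r} geometry differs from {first.name!r}"
            )
        out |= m.voxels
    return ROIMask(out, first.spacing.copy(), first.origin.copy(),
                   first.orientation.copy(), name="combined")


def expand_mask(mask: ROIMask, margin_mm: float) -> ROIMask:
    """Isotropic physical expansion: a voxel is included iff its Euclidean
    distance (mm, anisotropic spacing respected) to the original mask is
    <= `margin_mm`. Distance-transform semantics, not voxel dilation."""
    if margin_mm < 0:
        raise ValueError("margin_mm must be >= 0")
    if margin_mm == 0 or not mask.voxels.any():
        grown = mask.voxels.copy()
    else:
        dist = ndimage.distance_transform_edt(~mask.voxels, sampling=mask.spacing)
        grown = dist <= margin_mm
    return ROIMask(grown, mask.spacing.copy(), mask.origin.copy(),
                   mask.orientation.copy(),
                   name=f"{mask.name}+{margin_mm:g}mm" if mask.name else "expanded")


# ---------------------------------------------------------------------------
# NIfTI and CSV I/O (LPS internally, RAS in files)
# ---------------------------------------------------------------------------

_RAS_FROM_LPS = np.diag([-1.0, -1.0, 1.0, 1.0])


def _affine_lps(img_like) -> np.ndarray:
    m = np.eye(4)
    m[:3, :3] = img_like.orientation @ np.diag(img_like.spacing)
    m[:3, 3] = img_like.origin
    return m


def _decompose_affine(aff_lps: np.ndarray):
    lin = aff_lps[:3, :3]
    spacing = np.linalg.norm(lin, axis=0)
    orientation = lin / spacing
    return spacing, aff_lps[:3, 3].copy(), orientation


def save_image(image: VolumetricImage, path) -> None:
    nib.save(nib.Nifti1Image(image.voxels.astype(np.float32),
                             _RAS_FROM_LPS @ _affine_lps(image)), str(path))


def load_image(path) -> VolumetricImage:
    img = nib.load(str(path))
    spacing, origin, orientation = _decompose_affine(_RAS_FROM_LPS @ img.affine)
    return VolumetricImage(np.asarray(img.dataobj, dtype=float), spacing, origin, orientation)


def save_mask(mask: ROIMask, path) -> None:
    m = np.eye(4)
    m[:3, :3] = mask.orientation @ np.diag(mask.spacing)
    m[:3, 3] = mask.origin
    nib.save(nib.Nifti1Image(mask.voxels.astype(np.uint8), _RAS_FROM_LPS @ m), str(path))


def load_mask(path, name: str = "") -> ROIMask:
    img = nib.load(str(path))
    spacing, origin, orientation = _decompose_affine(_RAS_FROM_LPS @ img.affine)
    return ROIMask(np.asarray(img.dataobj), spacing, origin, orientation,
                   name=name or str(path))


def save_dvf(dvf: DeformationField, path) -> None:
    """Serialize a field as 4-D NIfTI, vector dimension last, components mm LPS."""
    m = np.eye(4)
    m[:3, :3] = dvf.orientation @ np.diag(dvf.spacing)
    m[:3, 3] = dvf.origin
    nib.save(nib.Nifti1Image(dvf.displacement.astype(np.float32), _RAS_FROM_LPS @ m), str(path))


def load_dvf(path) -> DeformationField:
    img = nib.load(str(path))
    spacing, origin, orientation = _decompose_affine(_RAS_FROM_LPS @ img.affine)
    return DeformationField(np.asarray(img.dataobj, dtype=float), spacing, origin, orientation)


def save_fiducials(points: PointSet, path) -> None:
    pd.DataFrame(
        {"label": points.labels,
         "x_mm": points.positions[:, 0],
         "y_mm": points.positions[:, 1],
         "z_mm": points.positions[:, 2]}
    ).to_csv(path, index=False)


def load_fiducials(path) -> PointSet:
    df = pd.read_csv(path)
    required = {"label", "x_mm", "y_mm", "z_mm"}
    if not required.issubset(df.columns):
        raise ValueError(f"fiducial CSV needs columns {sorted(required)}, got {list(df.columns)}")
    return PointSet(list(df["label"]), df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float))
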