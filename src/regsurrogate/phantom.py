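"""Deterministic digital pelvis phantom.

Generates a same-subject pair of CT-like and T2-MRI-like volumes at a
planning timepoint, organ ROI masks (prostate, proximal seminal vesicles,
penile bulb, bladder, rectum, plus pelvic bone shells and a soft-tissue
body), four implanted prostate fiducials, and a diagnostic-timepoint MRI
produced by warping the planning MRI through a known smooth ground-truth
deformation.  Every pipeline stage is thereby testable against analytic
truth with no external data.

Anatomy is a composition of ellipsoids rendered through per-modality
intensity tables; it is geometrically plausible rather than anatomically
realistic.  The default grid is 128x128x64 voxels at 1.25 x 1.25 x 2.5 mm —
the axial T2 acquisition geometry the phantom emulates — which generates in
a few seconds.

Noise models: CT receives additive Gaussian noise; MRI receives Rician-like
noise, the magnitude of the signal perturbed by complex Gaussian noise.
All randomness flows from the mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .image_model import (
    DeformationField,
    PointSet,
    ROIMask,
    VolumetricImage,
    combine_masks,
    expand_mask,
    resample_deformable,
)
from .local_rigid_dir import jacobian_determinant_map

__all__ = [
    "PhantomSpec",
    "PhantomSubject",
    "generate_planning_images",
    "generate_true_dvf",
    "generate_subject",
]

# organs are painted in order; later entries overwrite earlier ones
# (center mm, semi-axes mm) in the default 160 x 160 x 160 mm field of view
_DEFAULT_ORGANS = {
    "body": ((80.0, 80.0, 79.0), (75.0, 68.0, 78.0)),
    "bone_left": ((22.0, 85.0, 75.0), (14.0, 16.0, 30.0)),
    "bone_right": ((138.0, 85.0, 75.0), (14.0, 16.0, 30.0)),
    "bladder": ((80.0, 52.0, 98.0), (28.0, 22.0, 25.0)),
    "rectum": ((80.0, 120.0, 80.0), (13.0, 12.0, 45.0)),
    "prostate": ((80.0, 85.0, 72.0), (25.0, 22.0, 22.0)),
    "seminal_vesicles": ((80.0, 103.0, 96.0), (20.0, 10.0, 9.0)),
    "penile_bulb": ((80.0, 92.0, 38.0), (12.0, 11.0, 9.0)),
}

# CT in HU-like units; MRI in arbitrary T2-weighted units
_DEFAULT_CT = {
    "background": -1000.0, "body": 30.0, "bone_left": 700.0, "bone_right": 700.0,
    "bladder": 10.0, "rectum": -300.0, "prostate": 45.0,
    "seminal_vesicles": 38.0, "penile_bulb": 52.0, "fiducial": 3000.0,
}
_DEFAULT_MRI = {
    "background": 0.0, "body": 80.0, "bone_left": 55.0, "bone_right": 55.0,
    "bladder": 250.0, "rectum": 35.0, "prostate": 130.0,
    "seminal_vesicles": 170.0, "penile_bulb": 105.0, "fiducial": 0.0,
}

# structures whose masks are exported as ROIs
ROI_ORGANS = ("prostate", "seminal_vesicles", "penile_bulb", "bladder", "rectum")


@dataclass
class PhantomSpec:
    """Geometry, anatomy and noise parameters of the synthetic subject."""

    seed: int
    shape: tuple = (128, 128, 64)
    spacing: tuple = (1.25, 1.25, 2.5)
    organs: dict = field(default_factory=lambda: dict(_DEFAULT_ORGANS))
    ct_intensity: dict = field(default_factory=lambda: dict(_DEFAULT_CT))
    mri_intensity: dict = field(default_factory=lambda: dict(_DEFAULT_MRI))
    n_fiducials: int = 4
    fiducial_radius_mm: float = 10.0   # placement radius inside the prostate
    fiducial_render_mm: float = 1.9    # rendered sphere radius (~3 voxels across)
    boundary_smooth_mm: float = 1.5    # Gaussian smoothing of organ boundaries
    ct_noise_sigma: float = 12.0       # additive Gaussian, HU-like
    mri_noise_sigma: float = 6.0       # Rician-like, T2 units
    expand_margin_mm: float = 5.0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a random seed is mandatory")
        self.shape = tuple(int(n) for n in self.shape)
        self.spacing = tuple(float(s) for s in self.spacing)

    def geometry(self) -> VolumetricImage:
        return VolumetricImage(np.zeros(self.shape), self.spacing, (0.0, 0.0, 0.0))


@dataclass
class PhantomSubject:
    """The full synthetic dataset triad plus ground truth."""

    spec: PhantomSpec
    planning_ct: VolumetricImage
    planning_mri: VolumetricImage
    diagnostic_mri: VolumetricImage
    masks: dict                      # ROI name -> ROIMask (incl. combined/expanded)
    fiducials_planning: PointSet
    fiducials_diagnostic: PointSet
    true_dvf: DeformationField


def _paint_labels(spec: PhantomSpec) -> tuple:
    """Integer label volume (0 = background) and the name->label mapping."""
    geom = spec.geometry()
    x = geom.physical_grid()
    labels = np.zeros(spec.shape, dtype=np.int16)
    mapping = {}
    extent = geom.voxel_to_physical(np.asarray(spec.shape) - 1.0)
    for k, (name, (center, axes)) in enumerate(spec.organs.items(), start=1):
        c = np.asarray(center, dtype=float)
        a = np.asarray(axes, dtype=float)
        if np.any(c - a < -1e-9) or np.any(c + a > extent + 1e-9):
            raise ValueError(f"organ {name!r} extends outside the grid")
        inside = np.sum(((x - c) / a) ** 2, axis=-1) <= 1.0
        labels[inside] = k
        mapping[name] = k
    return labels, mapping


def _place_fiducials(spec: PhantomSpec, rng: np.random.Generator) -> PointSet:
    center = np.asarray(spec.organs["prostate"][0])
    axes = np.asarray(spec.organs["prostate"][1])
    pts, labels = [], []
    r = min(spec.fiducial_radius_mm, 0.6 * axes.min())
    for i in range(spec.n_fiducials):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        pts.append(center + u * r * rng.uniform(0.5, 1.0))
        labels.append(f"F{i+1}")
    return PointSet(labels, np.array(pts))


def _render(labels, mapping, table, spec, fiducials, rng, modality) -> VolumetricImage:
    geom = spec.geometry()
    vol = np.full(spec.shape, table["background"], dtype=float)
    for name, k in mapping.items():
        vol[labels == k] = table[name]
    # implanted markers as small spheres
    x = geom.physical_grid()
    for p in fiducials.positions:
        vol[np.sum((x - p) ** 2, axis=-1) <= spec.fiducial_render_mm**2] = table["fiducial"]
    if spec.boundary_smooth_mm > 0:
        vol = ndimage.gaussian_filter(vol, sigma=np.asarray(spec.boundary_smooth_mm) / spec.spacing)
    if modality == "ct":
        if spec.ct_noise_sigma > 0:
            vol = vol + rng.normal(0.0, spec.ct_noise_sigma, size=vol.shape)
    else:
        if spec.mri_noise_sigma > 0:
            re = vol + rng.normal(0.0, spec.mri_noise_sigma, size=vol.shape)
            im = rng.normal(0.0, spec.mri_noise_sigma, size=vol.shape)
            vol = np.hypot(re, im)
    out = geom.geometry_like()
    out.voxels = vol
    return out


def generate_planning_images(spec: PhantomSpec):
    """Render the planning-timepoint CT and MRI, organ ROI masks and the
    fiducial point set from one seeded generator."""
    rng = np.random.default_rng(spec.seed)
    labels, mapping = _paint_labels(spec)
    fiducials = _place_fiducials(spec, rng)
    ct = _render(labels, mapping, spec.ct_intensity, spec, fiducials, rng, "ct")
    mri = _render(labels, mapping, spec.mri_intensity, spec, fiducials, rng, "mri")
    geom = spec.geometry()
    masks = {
        name: ROIMask.from_image(geom, labels == mapping[name], name=name)
        for name in ROI_ORGANS
    }
    return ct, mri, masks, fiducials


# ---------------------------------------------------------------------------
# Ground-truth deformation
# ---------------------------------------------------------------------------

def _sample_bumps(spec: PhantomSpec, bumps: int, amplitude_mm: float,
                  scale_mm: float, rng: np.random.Generator):
    """Random Gaussian displacement bumps centered in the pelvic region."""
    margin = np.array([30.0, 30.0, 25.0])
    extent = spec.geometry().voxel_to_physical(np.asarray(spec.shape) - 1.0)
    lo, hi = margin, extent - margin
    out = []
    for _ in range(bumps):
        c = rng.uniform(lo, hi)
        a = rng.normal(size=3)
        a *= amplitude_mm / np.linalg.norm(a)
        out.append((c, a))
    return out


def _bump_field(bumps, points, scale_mm) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    d = np.zeros_like(pts)
    for c, a in bumps:
        w = np.exp(-np.sum((pts - c) ** 2, axis=-1) / (2.0 * scale_mm**2))
        d += w[..., None] * a
    return d


def generate_true_dvf(
    spec: PhantomSpec, bumps: int = 6, amplitude_mm: float = 5.0, scale_mm: float = 25.0
) -> DeformationField:
    """Sum of seeded random Gaussian displacement bumps.

    Invertibility is guaranteed by capping amplitude_mm below scale_mm/e —
    each bump's displacement gradient then stays well under 1 — and the
    minimum Jacobian determinant of the emitted field is checked and
    asserted positive.
    """
    if amplitude_mm < 0:
        raise ValueError("amplitude_mm must be >= 0")
    if amplitude_mm >= scale_mm / np.e:
        raise ValueError(
            f"amplitude_mm {amplitude_mm} violates the invertibility cap "
            f"scale_mm/e = {scale_mm / np.e:.3f}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 7]))
    bump_params = _sample_bumps(spec, bumps, amplitude_mm, scale_mm, rng)
    geom = spec.geometry()
    d = _bump_field(bump_params, geom.physical_grid(), scale_mm)
    dvf = DeformationField(d, geom.spacing.copy(), geom.origin.copy(), geom.orientation.copy())
    if bumps > 0 and amplitude_mm > 0:
        jmin = float(jacobian_determinant_map(dvf).voxels.min())
        assert jmin > 0, f"ground-truth field folds (min Jacobian {jmin:.3f})"
    dvf._bumps = bump_params      # analytic form, used for point transport
    dvf._scale_mm = scale_mm
    return dvf


def _transport_points(points: PointSet, dvf: DeformationField) -> PointSet:
    """Positions of planning-space points in the diagnostic (warped) image.

    The pull-back field satisfies diagnostic(x) = planning(x + d(x)); a
    feature at planning position p therefore appears at the x solving
    x + d(x) = p, found by fixed-point iteration on the analytic field.
    """
    bumps, scale = dvf._bumps, dvf._scale_mm
    out = []
    for p in points.positions:
        x = p.copy()
        for _ in range(200):
            step = p - _bump_field(bumps, x[None, :], scale)[0] - x
            x = x + step
            if np.linalg.norm(step) < 1e-9:
                break
        out.append(x)
    return PointSet(list(points.labels), np.array(out))


def generate_subject(
    spec: PhantomSpec, bumps: int = 6, amplitude_mm: float = 5.0, scale_mm: float = 25.0
) -> PhantomSubject:
    """Full synthetic subject: planning CT/MRI + masks + fiducials, the true
    deformation, and the diagnostic MRI = planning MRI warped by the truth
    with fresh noise."""
    ct, mri, masks, fid_plan = generate_planning_images(spec)
    dvf = generate_true_dvf(spec, bumps, amplitude_mm, scale_mm)

    # warp the noiseless planning MRI, then add fresh seeded Rician-like noise
    clean_spec = replace(spec, mri_noise_sigma=0.0, ct_noise_sigma=0.0)
    _, clean_mri, _, _ = generate_planning_images(clean_spec)
    diag = resample_deformable(clean_mri, spec.geometry(), dvf)
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 13]))
    if spec.mri_noise_sigma > 0:
        re = diag.voxels + rng.normal(0.0, spec.mri_noise_sigma, size=diag.voxels.shape)
        im = rng.normal(0.0, spec.mri_noise_sigma, size=diag.voxels.shape)
        diag.voxels = np.hypot(re, im)

    fid_diag = _transport_points(fid_plan, dvf)
    # self-check: transported points must satisfy x + d(x) = p analytically
    back = fid_diag.positions + _bump_field(dvf._bumps, fid_diag.positions, dvf._scale_mm)
    err = np.linalg.norm(back - fid_plan.positions, axis=1).max()
    assert err < 1e-6, f"fiducial transport self-check failed ({err:.2e} mm)"

    combined = combine_masks([masks[n] for n in ROI_ORGANS])
    masks = dict(masks)
    masks["combined"] = combined
    masks["expanded"] = expand_mask(combined, spec.expand_margin_mm)
    masks["expanded"].name = "expanded"
    return PhantomSubject(spec, ct, mri, diag, masks, fid_plan, fid_diag, dvf)
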