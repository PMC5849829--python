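"""ROI-restricted intensity-similarity metrics.

Pearson correlation and normalized mutual information (NMI) over the voxels
of a binary ROI, computed from an equal-width 2-D joint histogram, plus the
percent-change statistic comparing rigid against deformable registration.

Entropies use log base 2 (bits).  The default NMI variant, ``excess``, is
the Studholme ratio (H(A)+H(B))/H(A,B) minus 1, i.e. an excess-over-
independence scale on [0, 1]; absolute NMI magnitudes depend strongly on the
bin count, so the bin count is explicit everywhere with a default of 64.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .image_model import ROIMask, VolumetricImage

__all__ = [
    "JointHistogram",
    "UndefinedMetricError",
    "joint_histogram",
    "entropy",
    "pearson_in_roi",
    "nmi_in_roi",
    "percent_change",
    "NMI_VARIANTS",
]

log = logging.getLogger(__name__)

NMI_VARIANTS = ("excess", "studholme", "mi")


class UndefinedMetricError(ValueError):
    """A similarity metric is undefined for the given inputs."""


@dataclass
class JointHistogram:
    """2-D joint intensity histogram over in-mask voxel pairs."""

    counts: np.ndarray  # (B, B) integers
    edges_a: np.ndarray
    edges_b: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def marginal_a(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def marginal_b(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def _masked_pair(a: VolumetricImage, b: VolumetricImage, mask: ROIMask):
    if not (a.same_geometry(b) and a.same_geometry(mask)):
        raise ValueError("images and mask must share one geometry")
    va = a.voxels[mask.voxels]
    vb = b.voxels[mask.voxels]
    finite = np.isfinite(va) & np.isfinite(vb)
    if not finite.all():
        log.info("excluding %d non-finite in-mask voxels", int((~finite).sum()))
        va, vb = va[finite], vb[finite]
    return va, vb


def joint_histogram(
    a: VolumetricImage, b: VolumetricImage, mask: ROIMask, bins: int = 64
) -> JointHistogram:
    """Equal-width 2-D binning over the [min, max] in-mask range of each
    image; every in-mask voxel contributes exactly one count (top edge
    inclusive, as in `numpy.histogram2d`)."""
    if bins < 2:
        raise ValueError("bins must be >= 2")
    va, vb = _masked_pair(a, b, mask)
    if va.size < 1:
        raise ValueError("mask selects no (finite) voxels")
    # histogram2d needs a nonzero range even for constant inputs
    def _range(v):
        lo, hi = float(v.min()), float(v.max())
        return (lo, hi) if hi > lo else (lo - 0.5, hi + 0.5)
    counts, ea, eb = np.histogram2d(va, vb, bins=bins, range=[_range(va), _range(vb)])
    return JointHistogram(counts.astype(np.int64), ea, eb)


def entropy(counts) -> float:
    """Shannon entropy in bits of normalized histogram counts (any shape)."""
    c = np.asarray(counts, dtype=float).ravel()
    total = c.sum()
    if total <= 0:
        raise ValueError("entropy needs a positive total count")
    p = c[c > 0] / total
    return float(-np.sum(p * np.log2(p)))


def pearson_in_roi(a: VolumetricImage, b: VolumetricImage, mask: ROIMask) -> float:
    """Sample Pearson correlation over the in-mask voxel pairs."""
    va, vb = _masked_pair(a, b, mask)
    if va.size < 2:
        raise UndefinedMetricError("Pearson needs >= 2 in-mask voxels")
    if va.std() == 0 or vb.std() == 0:
        raise UndefinedMetricError("Pearson undefined: zero in-mask variance")
    r = np.corrcoef(va, vb)[0, 1]
    return float(np.clip(r, -1.0, 1.0))


def nmi_in_roi(
    a: VolumetricImage,
    b: VolumetricImage,
    mask: ROIMask,
    bins: int = 64,
    variant: str = "excess",
) -> float:
    """Normalized mutual information inside the ROI.

    variant ``studholme``: (H(A)+H(B))/H(A,B), in [1, 2];
    variant ``excess`` (default): studholme - 1, in [0, 1];
    variant ``mi``: H(A)+H(B)-H(A,B) in bits.
    """
    if variant not in NMI_VARIANTS:
        raise ValueError(f"unknown NMI variant {variant!r}; choose from {NMI_VARIANTS}")
    h = joint_histogram(a, b, mask, bins)
    hab = entropy(h.counts)
    if variant == "mi":
        return entropy(h.marginal_a) + entropy(h.marginal_b) - hab
    if hab == 0:
        raise UndefinedMetricError(
            f"NMI variant {variant!r} undefined: joint histogram has a single occupied cell"
        )
    ratio = (entropy(h.marginal_a) + entropy(h.marginal_b)) / hab
    return ratio if variant == "studholme" else ratio - 1.0


def percent_change(rigid_value: float, deform_value: float) -> float:
    """100 * (deform - rigid) / rigid."""
    if rigid_value == 0:
        raise ValueError("percent change undefined for a zero rigid value")
    return 100.0 * (deform_value - rigid_value) / rigid_value
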