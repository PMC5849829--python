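# Methods

## Geometric model

Images are 3-D scalar grids with physical geometry: spacing (mm/voxel),
origin, and an orthonormal direction matrix. Physical coordinates are
millimetres in the LPS convention; voxel indices are 0-based and the origin
is the **center** of voxel (0,0,0), matching NIfTI sform semantics and
removing half-voxel ambiguity. NIfTI files (RAS+ affines) are converted on
read/write. Interpolation is trilinear everywhere; the resampling fill value
defaults to the moving image's minimum so background stays plausible for
both CT (≈ −1000) and MRI (≈ 0). Deformation fields use the pull-back
convention — the field stores, per fixed-space voxel at x, the offset d(x)
such that the deformed image samples the moving image at x + d(x) — because
resampling then needs no field inversion.

ROI expansion ("the combined structure expanded by 5 mm") uses a Euclidean
distance transform in physical units rather than voxel-wise morphological
dilation: slices are 2.5 mm while in-plane spacing is 1.25 mm, so a
voxel-count dilation would be anisotropic in millimetres. The expansion is
3-D isotropic; an in-plane-only variant would be a one-line change
(`sampling` argument of the distance transform) but 3-D is the default.

## Fiducial rigid registration

Point sets are matched **by label**, never by proximity; a fiducial that
could not be localized is an absent row, and a label present in only one set
is an error naming it. The least-squares rigid fit is the closed-form
Kabsch/Umeyama solution: centroid subtraction, cross-covariance SVD, and a
determinant-sign correction that forces a proper rotation (no scaling, no
reflection). Degenerate configurations (< 3 pairs, collinear points) raise
a dedicated error. Cohort residual summaries pool **all per-fiducial
residuals** across subjects and use the sample (n−1) standard deviation;
this pairing reproduces both the published pooled mean (0.78 mm) and SD
(0.60 mm) from the printed per-fiducial values, which fixes it as the
default among the plausible pooling conventions.

## Deformable synthesis from local rigid alignments

The deformation at each voxel is the *normalized* Gaussian-weighted mean of
the displacements implied by the local alignments. A literal unnormalized
"distance-weighted sum" would shrink displacements toward zero far from all
centers even for a single pure translation, contradicting the degeneracy a
registration must have (one alignment ⇒ that alignment everywhere; all
alignments equal ⇒ the rigid field). Where the weight sum falls below a
floor (default 1e-6) the field falls back to the global rigid displacement;
continuity across that boundary is not guaranteed, so a Jacobian-determinant
map (central differences, one-sided at borders) is provided as a folding
diagnostic. The default mixing scale σ is the median nearest-neighbor
distance among alignment centers, adapting smoothness to alignment density;
it is overridable per alignment. All distances and weights are evaluated in
physical mm, never voxel units.

### Automatic local-alignment estimation

The clinical workflow's local alignments are placed manually. To run
unattended, a block-matching estimator finds translation-only local
alignments: for each seed, the spherical patch (radius 8 mm default) of the
fixed image is matched against moving-image patches over an exhaustive
voxel-grid search (±10 mm default) by maximizing Pearson correlation; σ is
set to the patch radius. Translations are the minimal faithful model of
manually pinned point correspondences and keep the search exhaustive and
deterministic. Two safeguards reject noise-driven matches: seeds whose best
correlation is below 0.5 are treated as structureless and skipped, and among
candidates within 0.01 of the peak correlation the smallest translation is
preferred, so statistically indistinguishable peaks cannot pull the field
away from the identity. In the pipeline, block matching runs between the
surrogate planning MRI and the rigidly pre-aligned diagnostic MRI — a
same-modality pair, where signed Pearson is a valid objective; matching
directly against the CT would invert local intensity relationships at some
tissue interfaces. This reuses the surrogate inside the registration, a
departure from the evaluation's strict independence that the manual clinical
procedure does not share; it is the price of automation and is why the
synthetic results are read qualitatively (deformable beats rigid), not as
absolute metric values.

## Similarity metrics

Pearson correlation and NMI are computed over in-mask voxels only; non-finite
voxels (e.g. resampling fill) are excluded with a logged count. The joint
histogram uses equal-width binning over each image's in-mask range, top edge
inclusive, 64 bins by default — NMI magnitudes depend strongly on binning, so
the count is explicit everywhere. Entropies are log-base-2 (bits). The
default NMI variant is `excess`: the Studholme ratio (H(A)+H(B))/H(A,B)
minus 1, an excess-over-independence scale on [0,1]. The published
per-subject NMI values (0.035–0.152) are incompatible with the raw Studholme
range [1,2], so the excess scale is the only printed-value-compatible
convention; absolute NMI values are nevertheless *not* treated as
reproducible targets — only their percent changes are, since the exact
normalization and bin count behind the published absolute values are
unknown.

## Cohort statistics

Paired two-sided Student's t-tests (sample SD, dof = n−1), with zero-variance
differences flagged degenerate (p = 1 for identical samples, p = 0 for a
constant nonzero shift) rather than raised. "Average percent improvement" is
ambiguous — the mean of per-subject percent changes and the percent change
of the cohort means differ (34.84% vs 27.80% for the published expanded-ROI
NMI column; the published headline of 27.37% matches neither recomputation
from the rounded table, plausibly because it was computed pre-rounding) — so
**both aggregations are always emitted side by side** and no silent choice
is made. Improvement counts use pct_change > 0 strictly. Report tables round
residuals to 2 decimals, metric values to 3, percent changes to 2; footers
are recomputed from the emitted rows on every run.

## Digital pelvis phantom

The phantom emulates the study conditions: a same-subject planning CT and
T2-MRI pair on one 128×128×64 grid at 1.25 × 1.25 × 2.5 mm (the axial T2
acquisition geometry), four gold fiducials implanted in the prostate, organ
ROIs, and a diagnostic MRI at an earlier timepoint related to the planning
MRI by a known smooth deformation. Anatomy is a painter's-order composition
of ellipsoids (soft-tissue body, two pelvic bone bodies, bladder, rectum,
prostate at ≈ 50.7 mL matching the cohort mean, proximal seminal vesicles,
penile bulb) rendered through per-modality intensity tables (CT HU-like:
air −1000, soft tissue 10–60, bone 700, fiducial 3000; MRI T2-like:
bright urine 250, prostate 130, fiducial signal void 0), Gaussian-smoothed
at boundaries (1.5 mm). CT noise is additive Gaussian (σ = 12 HU); MRI noise
is Rician-like, the magnitude of the signal perturbed by complex Gaussian
noise (σ = 6) — the standard modality noise models. Fiducials are rendered
as ≈ 3-voxel-diameter spheres, but their point coordinates are carried as
metadata; localizing them from images is out of scope, as in the clinical
workflow.

The ground-truth deformation is a sum of seeded random Gaussian displacement
bumps (default 6 bumps, 5 mm amplitude, 25 mm scale, centered in the pelvic
region). Invertibility is guaranteed by requiring amplitude < scale/e —
each bump's displacement gradient then stays well below 1 — and the minimum
Jacobian determinant of every emitted field is asserted positive. Fiducials
are transported to the diagnostic timepoint by solving x + d(x) = p with
fixed-point iteration on the analytic bump sum (self-checked to < 1e-6 mm).
The diagnostic MRI is the *noiseless* planning MRI warped through the field,
with fresh seeded Rician-like noise added afterwards, so its noise is
independent of the planning image's. All artifacts are bit-reproducible
under a fixed seed.

What the phantom does **not** emulate: real soft-tissue biomechanics
(bladder/rectum filling), MRI pulse-sequence physics, intensity
inhomogeneity, oblique acquisitions, or cross-visit intensity drift. A
passing synthetic cohort therefore shows that the pipeline's machinery is
correct and that the deformable model recovers smooth deformations it can
represent — not that it would perform identically on clinical data.

## Problem sizes and numerical choices

The synthetic validation cohort is 13 subjects (matching the clinical cohort
size) at the default grid; one subject runs in ~10–15 s on a single core, so
a cohort completes in a few minutes. Pipeline defaults: 4×4×4 block-matching
seed grid spanning the expanded ROI's bounding box (inset so search windows
stay inside the volume), patch radius 8 mm, search ±10 mm, 64 histogram
bins, weight floor 1e-6. Trilinear sampling outside the voxel-center
bounding box returns the fill value exactly (no partial blending). The
collinearity test in the rigid fit uses a rank tolerance scaled by the
configuration's extent. Histogram construction relies on `numpy.histogram2d`
(top-edge-inclusive); constant in-mask images get a degenerate unit-width
bin range so every voxel still lands in exactly one cell.

## Known limitations

- The automatic alignment estimator is translation-only; rotational local
  anatomy changes are approximated by neighboring translations.
- The surrogate doubles as the block-matching reference (see above).
- The fallback boundary of the synthesized field can be discontinuous by
  construction; the Jacobian map flags any folding.
- Absolute NMI values depend on bin count and ROI size and are not
  comparable across studies.
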