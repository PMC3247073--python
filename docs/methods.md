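# Methods

## Coordinate conventions

All patient-frame coordinates are DICOM LPS millimetres. Voxel indices are
0-based `(slice, row, column)` triples; the geometry origin is the *center*
of voxel (0,0,0) (ImagePositionPatient semantics). The forward map is the
standard DICOM affine; its inverse uses the orthonormality of the direction
matrix. Nearest-voxel rounding is round-half-even per axis so ties resolve
deterministically. Sheared (non-orthogonal) acquisitions and gantry-tilt
correction are out of scope; geometry construction rejects non-orthogonal
axes at 1e-6 and non-unit axes at 1e-9.

Inter-slice spacing is always derived from successive slice positions
projected onto the slice normal, never from the SliceThickness tag: gapped
or overlapping series are common, and positions are authoritative. Series
with position gaps deviating more than 1e-3 mm from uniform are refused.

## Rigid registration and the RMS gate

Paired-point registration solves `min_{R,t} Σ ||R p_i + t − q_i||²` in
closed form: centroid alignment plus orthogonal Procrustes via SVD of the
centered cross-covariance, flipping the sign of the smallest singular
direction when the unconstrained optimum is a reflection. This is exact and
deterministic; no iterative optimization is involved. The reported
`rms_error` is the fiducial registration error (FRE) over the fitting
markers — the number navigation systems display at registration time.
Target registration error elsewhere in the volume is out of scope.

Degenerate inputs are rejected up front: fewer than 3 pairs, image-side
duplicates closer than 1e-6 mm, and collinear configurations (second
singular value of the centered set below 1e-9 relative). Three non-collinear
pairs determine the transform; clinical practice uses four markers, which is
the fixture default.

The acceptance gate defaults to 0.8 mm, the upper end of the customary
0.5–0.8 mm band, and is exposed as a parameter since the band is a site
policy rather than a mathematical constant. At a realistic 0.25 mm per-axis
localization noise on four markers spanning ~100 mm, the expected FRE is
`σ √(3(1 − 2/N)) ≈ 0.31 mm` — comfortably inside the gate, which the
Monte-Carlo helper reproduces.

## Sentinel encoding and extraction

Conventional CT intensities end near 3100 HU; 12-bit unsigned storage with
intercept −1024 tops out at exactly 3071 HU. Marks are written at 3500 HU,
recovered at a 3200 HU threshold — chosen as the value with maximal margin
to both the native ceiling (~100+ HU) and the sentinel (300 HU), so small
downstream perturbations (rescale rounding, nearest resampling) cannot flip
a voxel across the threshold.

Design choices:

- **One voxel per point** by default; a spherical `mark_radius_mm` is
  available purely as a display aid for platforms that render single voxels
  poorly.
- **Separability is verified, not assumed.** If any native voxel exceeds
  the declared native ceiling (e.g. dense metal artifact), encoding fails
  loudly rather than producing marks thresholding could confuse with
  anatomy. Voxels already at exactly the sentinel value are treated as
  existing marks, which makes encoding idempotent.
- **Bit-depth widening.** When the sentinel is unrepresentable at the
  source depth, the stored encoding widens to signed 16-bit, slope 1,
  intercept −1024 — the minimal change keeping native values and the
  sentinel jointly representable. All other attributes are preserved;
  rewritten series carry fresh SOP/series instance UIDs but the same study
  and frame-of-reference UIDs, so they never collide with the originals yet
  stay co-registered. The whole series is rewritten (not only affected
  slices) for self-consistency.
- **Collisions** (two points rounding to one voxel) merge by default with a
  logged warning — specimens closer than one voxel are clinically
  plausible and a hard failure would block export; an error policy exists.
- **Labels travel in a sidecar.** A single sentinel value cannot carry
  names, sequence numbers or histology, so the export writes the selected
  points as a flat table next to the series. Only confirmed tumor-positive
  points are exported; unknown histology is excluded deliberately (a
  false-positive mark would corrupt radiotherapy planning), and no benign
  channel is provided.

The positional round-trip error of encode→extract is bounded by half the
voxel diagonal (quantization of the nearest-voxel map); matching for the
error report is greedy by increasing pair distance.

## Segmentation, margins, mirroring

Margin augmentation is metric: a voxel joins the augmented mask iff its
center lies within `margin_mm` (Euclidean, mm) of a true voxel center,
computed with the exact Euclidean distance transform using the grid spacing
as sampling, so anisotropic voxels are handled correctly. The default 10 mm
reflects the ≥1 cm resection-margin convention. "In every dimension" could
also be read per-axis; a box (Chebyshev) variant is exposed via
`metric="box"` — it is a superset of the Euclidean result along diagonals.
The surface clearance of the Euclidean dilation is at least the margin at
voxel-center resolution (on a 1 mm grid the minimum achievable
center-to-center distance above 10 mm is √101 ≈ 10.05 mm).

Mirroring reflects across a sagittal plane `x = const` and resamples by
nearest neighbor; on grid-aligned planes it is an exact involution. Voxels
whose reflections leave the grid are counted and reported. Manual brush
segmentation is out of scope; masks enter via thresholding or file import.

## Fusion

Volume fusion samples each target voxel from the rigidly transformed
source, nearest or trilinear, with −1024 HU fill outside the source.
Trilinear output is rounded to integer HU so it remains representable as
stored pixels. Voxels whose nearest source sample lies in the sentinel band
are always taken nearest-neighbor: interpolation would average a 3500 HU
mark with its neighbors and drop it below the extraction threshold — the
one resampling failure mode that silently destroys the encoded information.
The lossless alternative, `fuse_points`, transforms the point table
directly; the two paths agree within the composed quantization bound (half
source-voxel diagonal + half target-voxel diagonal). Intensity-based
(mutual-information) and deformable fusion are out of scope.

## The phantom: what it emulates, and what it does not

The generator rasterizes an ellipsoidal head (default semi-axes
50 × 58 × 26 mm, fitting a 64 × 128 × 128 grid at 1 mm with margin), a 4 mm
bone shell at 1200 HU around 40 HU soft tissue with mild Gaussian texture
(σ = 8 HU, rounded to integers), air background at −1000 HU, one 8 mm
tumor sphere at 300 HU (a contrast-enhancing lesion, cleanly separable from
soft tissue by thresholding), and four 2 mm-radius fiducial blobs at
3000 HU — metal-bright yet under the 3071 HU ceiling, preserving the
separability premise. Everything is clipped to [−1024, 3071] HU and stored
12-bit unsigned. Generation is a pure function of the spec including its
seed.

The navigation simulator draws a uniformly random rigid transform for the
patient-vs-tracker pose, perturbs fiducial touch-offs with isotropic
Gaussian noise (0.25 mm per axis as the realistic default), and scatters
specimen points uniformly in a ball around the tumor, assigning
malignant/benign/unknown histology at 0.4/0.4/0.2 — enough malignant points
to exercise selection while keeping all three classes present.

Not emulated: realistic CT noise spectra, beam hardening and metal
artifacts, soft-tissue deformation between imaging and surgery, and
tracking-system bias. Passing tests therefore demonstrate the geometric and
encoding pipeline is correct under rigid geometry and clean intensities;
they do not certify clinical localization accuracy, which depends on the
hardware and tissue effects excluded here.

## Problem sizes and numerics

Tests and the acceptance script use the 64 × 128 × 128 default phantom for
end-to-end runs and a 32 × 64 × 64 variant for IO-heavy unit tests;
registration Monte-Carlos use 1000 replicates (200 for the noise-monotonicity
check). The margin clearance quantity is computed on a 41³ grid holding a
5 mm sphere dilated by 10 mm. Floating-point tolerances: 1e-9 mm for
geometric round trips, 1e-12 for Procrustes-vs-brute-force residual
agreement, exact integer equality for HU values after write/read. Table IO
writes 17 significant digits and parses with correctly rounded floats so
point tables round-trip losslessly.
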