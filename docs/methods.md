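# Methods

`i2m` converts a CBCT scan of an elastomeric dental impression into a
positive digital model, measures surface accuracy against a reference
mesh, and analyzes replica-technique crown-fit measurements. This note
documents the models, the tunable parameters, the synthetic data used
for validation, and the numerical choices made where the design was
genuinely open.

## Segmentation model

The intensity histogram of a CBCT impression scan is treated as a
K-component Gaussian mixture: an air/background class and a
polyvinylsiloxane (PVS) material class (K = 2 by default; K = 3 adds a
tray-material class). The mixture is fitted by expectation-maximization
**on the binned histogram** — bin centers weighted by counts — so one
iteration costs O(n_bins) regardless of volume size. Initialization
splits the bins at the K−1 weighted quantiles, making the fit fully
deterministic (no random restarts). Safeguards: a variance floor of
(bin width)²/4 prevents component collapse; iteration stops when the
relative log-likelihood gain falls below `tol = 1e-6` or after
`max_iter = 500` iterations; the log-likelihood is non-decreasing by
the EM guarantee and the fitted components are stored with ascending
means.

The segmentation **valley** is the interior minimizer of the fitted
mixture density between the two highest-weight component means (for
exactly two components this is the intersection point of the weighted
class densities). It is located by a 4096-point grid scan refined by
bounded scalar minimization; if the density has no interior minimum the
classes are reported as not separable.

### Material calibration

The valley is a statistical feature of the histogram, not the physical
material border. Partial-volume averaging skews boundary voxels, and in
low-noise scans the density between the modes is nearly flat, so the
valley can sit far from the 50%-occupancy intensity. The pipeline
therefore applies an additive, material-specific **calibration offset**:
`threshold = valley + offset`. `fit_calibration` fits the offset from a
reference scan whose true surface is known, by a deterministic 1-D
search (13-point coarse grid over ±0.9 of the valley-to-class-mean
gaps, then parabolic refinement) minimizing the mean unsigned distance
between the iso-surface at `valley + offset` and the reference mesh.
The shipped default offset is 0. On the synthetic phantoms the offset
fitted on one die geometry transfers to another (same intensity model),
which is the premise of calibrating per material rather than per scan.

The binary mask at the threshold is restricted to the **area of
conversion**: the largest 26-connected component, cropped to its
bounding box padded by two voxels. This removes noise speckles and
shrinks the marching-cubes domain.

## Surface extraction and smoothing

Iso-surfaces are extracted with topology-consistent (Lewiner) marching
cubes and linear sub-voxel interpolation; vertices map to millimetres
via `world = origin + index · spacing` (voxel centers). Face winding is
fixed so normals point out of the high-intensity material. The
impression surface is the geometric negative of the dentition, so the
**positive conversion** is a pure orientation flip of the same surface —
no Boolean re-meshing — and the signed volume changes sign.

Smoothing uses Taubin's λ|μ schedule with the uniform umbrella
operator: each iteration applies a shrinking Laplacian step with factor
λ and an inflating step with factor μ, subject to the pass-band
condition 1/λ + 1/μ > 0. Defaults λ = 0.33, μ = −0.34, 30 iterations
(pass-band frequency ≈ 0.09) denoise without the volume shrinkage of
plain Laplacian smoothing (on a 2562-vertex unit sphere, 50 Taubin
iterations change volume by ~0.4% where 50 Laplacian steps shrink it by
~13%). Mesh cleanup merges vertices within 1e-9 mm, removes degenerate
faces and drops connected components below 1% of total area.

## Deviation measurement

Registration mimics inspection software: an "initial alignment"
(matching centroids and principal axes) followed by a "best fit"
(iterative closest point with Kabsch least-squares updates, optional
worst-10% trimming, stop when the RMS improves by less than
1e-4 × the reference bounding-box diagonal). The initial alignment uses
**area-weighted** (face-centroid) covariance rather than vertex
covariance: vertex statistics depend on tessellation density, and two
meshes of the same surface can otherwise disagree on their principal
axes. Among the four proper-rotation sign assignments of the principal
axes the one with the smallest symmetric mean nearest-vertex distance
is kept.

Deviations are signed point-to-surface distances from test vertices to
the nearest point on any reference triangle (exact point-triangle
projection with a KD-tree candidate prefilter; the sign comes from the
reference's outward normal at the nearest point, positive = outside).
They are reported in μm with RMS / mean / min / max summaries,
optionally restricted to a user-specified sphere or box crop standing
in for prepared-area isolation. The correspondence direction is
test → reference (asymmetric), matching inspection-software convention.

## Gap statistics

Each crown specimen is sectioned mesiodistally (MD) and buccolingually
(BL); per section the replica-film thickness is recorded at the
marginal area (MA), axial area (AA) and axio-occlusal angle (AOA) on
both lateral sides plus once at the occlusal area (OA) on the midline:
4 MA + 4 AA + 4 AOA + 2 OA = 14 records per specimen (so 16 specimens
give 64 marginal, 160 internal, 224 total records). Recording OA once
per section is fixed by that arithmetic. Descriptives use n−1 standard
deviations and linear-interpolation (type-7) quantiles, with the IQR
reported both as the width Q3−Q1 and as the (Q1, Q3) pair so either
convention can be inspected.

Because gap thicknesses are right-skewed, inference is rank-based:
Mann-Whitney U for MD-vs-BL contrasts, Friedman across the four point
types on specimen means, pairwise Wilcoxon signed-rank contrasts
(unadjusted by default; Bonferroni optional), and an advisory
D'Agostino omnibus normality screen. Exact two-sided p-values come from
the full null distributions computed by count recurrences (the
Mann-Whitney U recurrence and the signed-rank subset-sum generating
function) when samples are small (n ≤ 10 per group, n ≤ 12 pairs) and
tie-free; otherwise tie-corrected normal approximations with continuity
correction are used. The exact paths are verified bit-for-bit against
brute-force enumeration in the tests.

## Synthetic phantom

No scanner data ships with the package; every stage is validated on a
synthetic phantom. The ground truth is a watertight solid of
revolution standing in for a prepared tooth: a tapered abutment wall
(default total convergence 12°), a concave quarter-circle chamfer
margin (radius 4 mm, depth 0.5 mm), and a spherical-cap occlusal dome
whose height is the difference of the functional and non-functional
occlusal reductions (defaults 1.5 and 1.0 mm, following common
crown-preparation clearance guidance). The parametrization is a
geometric stand-in, not an anatomical tooth; two plain domed cylinders
can be added as neighbouring teeth.

The impression is the material complement of the die inside a tray
region (the bounding box dilated by 1 mm — only the material/air
interface matters downstream). Voxelization samples
`supersample_factor³` points per voxel (inside tests against z-slab
cross-section polygons), giving exact partial-volume occupancy
fractions at the boundary; per-axis spacing is snapped so the grid
tiles the tray exactly (within half a voxel of the requested 0.1 mm).
Intensities blend two Gaussian classes by occupancy — defaults
air = 0 ± 40, PVS = 700 ± 40 in arbitrary CBCT grayscale units, chosen
to give two well-separated histogram modes — with seeded noise.

What the phantom does **not** emulate: beam hardening, scatter,
cone-beam reconstruction artifacts, device-specific grayscale
nonlinearity, or anatomical shapes. Passing the end-to-end tests shows
the conversion chain is sub-voxel-accurate under Gaussian class noise
and partial-volume blur; it does not certify accuracy on scanner data
with structured artifacts.

The gap simulator draws thicknesses from per-point-type lognormals.
Default medians/shape parameters (MA: 86 μm, σ=0.93; AA/AOA: 110 μm,
σ=0.55; OA: 245 μm, σ=0.30) were chosen once so the simulated area
means echo the magnitudes reported for replica measurements of
3D-printed interim crowns (marginal ≈ 133 μm, occlusal ≈ 256 μm) while
keeping realistic right-skew; they are generator settings, not
re-measurements.

## Validation problem sizes

The shipped tests and the acceptance script use: a 10⁶-sample histogram
for EM recovery; ~7·10⁵-voxel phantom volumes at 100 μm isotropic
spacing for the end-to-end conversion (calibration fitted on a separate
reference die, then applied — the full protocol); 2000 simulated
16-specimen tables for the null rejection rate and 500 for the
MA-vs-OA power; 2562-vertex spheres for smoothing. These sizes were
chosen so each property is measured with comfortable statistical margin
while the whole suite remains quick on a laptop.

## Known limitations

- The calibration offset is additive and global; spatially varying
  bias (e.g. from scatter) is out of scope.
- ICP uses nearest-vertex correspondences; on very coarse references
  the registration inherits tessellation error (deviations themselves
  always use exact point-to-triangle distances).
- The valley definition assumes two dominant, separable intensity
  classes; overlapping classes are rejected rather than guessed.
- DICOM support covers single-frame, uniformly spaced, uncompressed
  series only.
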