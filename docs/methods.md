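# Methods

This note documents the models, numerical choices and limitations of
`lumenline`. It is the package's own account of what it computes; every
number quoted here is produced by the test suite or
`scripts/acceptance.py`.

## The centerline model

A centerline is a curve threading the lumen such that each point is the
geometric center of the lumen section orthogonal to the curve's local
tangent. This is a fixed-point definition — the section depends on the
tangent, which depends on the curve — and the algorithm solves it by
iteration:

- **Initialization.** Per-z-slice foreground centroids give c₀,ₖ, one
  point per slice index k. Empty slices at the ends are trimmed;
  interior empty slices are filled by linear interpolation. Each
  coordinate sequence is Gaussian-smoothed over k (σ = 20 samples by
  default).
- **Tangents.** Second-order finite differences: central differences in
  the interior, the one-sided stencils (−3f₀ + 4f₁ − f₂)/2 at the ends,
  normalized to unit length. Degenerate (zero-length) stencils inherit
  the nearest valid tangent.
- **Orthogonal re-centering.** At each point a square planar grid
  (spacing 1 voxel) orthogonal to the tangent is resampled from the
  binary mask by trilinear interpolation; samples outside the volume
  read 0. The grid is thresholded at 0.5 — the half-voxel level of an
  interpolated {0,1} field — and the 8-connected component nearest the
  current point is selected; its centroid, mapped back to 3D, is the
  candidate c_j,k. An empty slice is a gap: the previous point is
  carried forward.
- **Relaxation.** c_{i+1,k} = (1 − β) c_{j,k} + β c_{i,k}, then
  Gaussian smoothing of the three coordinate sequences. β = 0.5 damps
  the oscillation that arises when oblique slices near a bulge or
  appendage throw the centroids sideways; β up to 0.9 is appropriate
  for debris-contaminated masks.
- **Termination.** The residual ρ (mean pointwise distance between
  successive iterates) is compared to μ = 0.3 voxel. Convergence below
  one voxel length is the natural scale: the centerline is then stable
  to less than the data resolution. Non-convergence within `max_iter`
  (default 100) returns the last iterate with a warning, never an
  exception.

### Parameters

| parameter | default | units | role |
|---|---|---|---|
| β | 0.5 | — | relaxation weight on the previous iterate |
| σ | 20 | samples along k | curve smoothing width |
| μ | 0.3 | voxel lengths | convergence threshold on ρ |
| max_iter | 100 | — | iteration cap |
| slice spacing | 1 | voxel | in-plane sample spacing |
| half-extent | 1.5 × max per-z bbox half-diagonal | voxel | slice window radius |

The slice half-extent guarantees the orthogonal window never clips the
lumen even where the tube is oblique or swollen.

## Numerical choices

**Boundary rule for curve smoothing.** Gaussian smoothing with a
reflecting boundary contracts a straight curve at its ends on every
iteration, so the residual would decay geometrically without the curve
converging to anything meaningful. The smoother therefore pads each
coordinate sequence by linear extrapolation (slope fitted over the
outermost ~σ samples) before filtering: affine sequences are exact fixed
points, so a straight centerline is left untouched and repeated
smoothing only suppresses wiggles. With this rule the axis-aligned tube
terminates at the first residual check with ρ ≈ 1e-15, as the
termination contract requires.

**Curvature bias.** Gaussian smoothing pulls a curved line toward its
chord by roughly σ²κ (κ the curvature). For the default bent phantom
(20° over 200 voxels, κ ≈ 1/573) this is ≈ 0.7 voxel at σ = 20 and is
the dominant term in the converged RMSE of ≈ 0.43 voxel on bent
phantoms. Smaller σ reduces the bias but tracks noise more closely; the
default follows the stabilization-first philosophy of the method.

**Area estimator.** Slice areas are measured by partial-volume
summation: the trilinearly interpolated mask values are summed over the
selected component and a 2-pixel surrounding ring. Counting thresholded
samples instead is unstable at small radii — the digitized boundary
flips whole pixel rows as the sampling grid shifts by sub-voxel phases,
producing up to ±7 % jumps at r ≈ 8; the partial-volume sum is stable to
about ±1.5 % there because trilinear interpolation conserves the mask's
mass. The thresholded grid is still what defines connectivity and
component selection.

**Component selection.** In multi-component slices (e.g. where a plane
also cuts a bifurcation appendage) the component nearest the current
centerline point wins; ties break toward the smaller centroid distance,
then the larger area. This rule is what removes the appendage bulge:
once the slices separate the appendage from the main lumen, its pixels
stop contributing to the centroid.

**Bin-integrated Gaussian fits.** Histogram peak decomposition fits the
amplitude–mean–sigma parameterization through the *bin-integrated*
Gaussian mass rather than the curve value at the bin center. For peaks
wider than a few bins the two are identical; for peaks narrower than a
bin (which arise after strong prefiltering) the integrated model remains
exact where the pointwise model fails. Default initialization places
components on the highest well-separated local maxima with widths
estimated from the detected peak FWHM.

**Gaussian prefilter boundary.** The σ = 2 prefilter uses a periodic
(wrap) boundary so the normalized kernel conserves total intensity
exactly; the volume mean is preserved to numerical precision, which
keeps histogram comparisons before/after filtering on the same scale.

**Ball morphology via distance transforms.** Erosion and dilation by a
radius-r Euclidean ball are computed from exact Euclidean distance
transforms (erosion: distance-to-background > r with the outside
counting as background; dilation: distance-to-foreground ≤ r). This is
bit-identical to morphology with an explicit ball structuring element —
verified against it in the tests — but scales to r = 20 where a 41³
structuring element is impractical.

**Joint-histogram binning.** 256 bins per axis by default over the
1st–99th intensity percentiles, with values clipped into range so every
voxel is counted and the marginals are exactly recoverable from
row/column sums. Class-recovery tests use the full range to avoid
truncating extreme-class peaks.

## The phantom generator

Phantoms emulate the geometry the pipeline targets: bent tubes (circular
arcs), local swellings and constrictions (Gaussian radius bumps), a
blind-ended cylindrical appendage standing in for a bifurcation stub,
and an oblique cylinder as the obliquity stress case. A voxel is
foreground iff its center lies within r(t*) of the curve at the locally
nearest curve point t* (distance to the sampled polyline's segments,
radius interpolated along the segment); no antialiasing, so an
exhaustive per-voxel oracle reproduces the generator exactly.

Default geometries:

- *bent*: length 200 voxels, radius 8, 20° arc;
- *swelling benchmark*: the bent tube with two swellings to r = 14 and
  one constriction to r = 5 (Gaussian bumps wide enough that the
  union-of-spheres envelope stays within 5 % of π r² — steeper flanks
  would inflate the rasterized surface by (1 + (dr/ds)²));
- *bifurcation*: a straight parent (radius 8, length ~200) with a long
  thin appendage (radius 3, length 60, 64° off-axis). The parent is
  kept straight so the converged deviation isolates the appendage's
  influence from the smoothing curvature bias; the appendage is long
  and thin because its *volume* drives the initial centroid bulge
  (> 3 voxels) while its *cross-section* sets the small residual bias of
  the few orthogonal slices where it merges with the parent section near
  the attachment (< 1 voxel converged).
- *shrinkage pair*: straight tubes (voxel length 10 µm) whose baseline
  radius carries two gentle bumps as alignment features; the "after"
  tube reproduces a 0.5 mm-cropped portion with areas scaled 0.85 /
  0.65 / 0.35 on three segments.
- *two-modality tissue phantom*: four tissue classes (embedding medium,
  fibrous tissue, vessel wall, residual plaque) with per-class Gaussian
  intensities per modality. Options add spatially correlated background
  noise (unit variance preserved) and a heavy-tailed outlier fraction,
  emulating reconstruction speckle: with i.i.d. Gaussian noise alone the
  unfiltered histogram is *exactly* a Gaussian mixture and prefiltering
  could not reduce the fit residual, which would misrepresent real
  tomograms. The prefilter scenario uses correlation length 1.0 voxel
  and 5 % outliers.

What the phantoms do **not** emulate: tomographic artefacts (streaks,
phase wrapping, rings, air bubbles), realistic plaque morphology,
intensity gradients along the specimen, and true flow-splitting
bifurcations (the appendage is blind-ended). Passing tests therefore
demonstrate the geometric correctness and convergence of the algorithms,
not robustness to every artefact of measured data.

## Evaluation conventions

Deviations from the analytic centerline exclude points that project onto
the curve endpoints: the rasterized tube carries hemispherical end caps
beyond the parametric curve, and stations there have no orthogonal
counterpart on the truth. Shrinkage segment medians are evaluated
0.12 mm inside the segment boundaries, away from interpolation blur at
the scale steps and from the end caps. Problem sizes (grids of 64–128
voxels per side, tubes of ~200 voxels length) were chosen as the
smallest geometries on which the discretization error bounds above hold
with margin.

## Known limitations

- The residual ρ is a mean over stations, so a strongly localized
  deviation can fall below μ while still being visible; the bifurcation
  phantom is sized so the bulge is resolved before termination, but on
  very long vessels with small appendages the converged centerline may
  retain a sub-voxel local bias near the attachment.
- The alignment of two area profiles by normalized cross-correlation
  recovers a constructed 0.5 mm offset to within a few station spacings
  (0.47 mm on the default pair); piecewise area scalings deform the
  correlation peak slightly. A user-supplied fixed offset overrides the
  search.
- Region growing uses a fixed intensity tolerance around the seed mean
  with 26-connectivity — the simplest criterion consistent with seeded
  growth; adaptive or gradient-based criteria are out of scope.
- The median filter's kernel "size 15" is implemented as a 15³ cube
  (edge length); the opening's "20 voxels" as the ball radius. Both are
  configurable where other readings are preferred.
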