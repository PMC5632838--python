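# Methods

## Problem setting

During MR-guided high-intensity focused ultrasound (MRg-HIFU) ablation of
abdominal targets, physiological motion occurs on three time-scales:
quasi-periodic respiration (3–5 s cycles, addressed first-order by
navigator gating), slow irreversible drifts over minutes (digestion,
muscle relaxation; several mm over an hour), and spontaneous motion (out
of scope here, as in the clinical work-flow this package models).  The
package implements the image-based machinery that keeps a therapy
spatially consistent despite the first two: dense deformable registration
between the scans acquired throughout a session, propagation of the
sonication plan *down-stream* into the current anatomy, and propagation
of the measured thermal dose *up-stream* into the planning frame.

## Registration engines

Both engines minimise a variational energy over a dense displacement
field u, in world millimetres, with a first-order quadratic regulariser:

```
E(u) = D(I, J∘(id+u)) + α Σ_r ‖∇u(r)‖²
```

**Mono-modal (optical flow).**  D is the L1 intensity-constancy term
Σ_r |I(r) − J(r+u(r))|.  The non-differentiable |·| is smoothed with a
Charbonnier function √(x²+ε²) and handled by iteratively reweighted least
squares: each outer iteration warps J, linearises the residual, and
solves the coupled per-voxel normal equations with vectorised Jacobi
sweeps (closed-form 2×2/3×3 per-voxel inverses; Neumann boundary for the
Laplacian).  ε defaults to 0.01 of the normalised intensity range; in the
ε→0 limit the scheme minimises the exact L1 functional.

**Multi-modal (MIND).**  Each voxel receives a modality-independent
neighbourhood descriptor
`MIND(I,r,γ) = exp(−D_p(I,r,r+γ)/V(I,r)) / Z`, where D_p is the SSD
between the patches of half-width p around r and r+γ, V is the mean of
D_p over the one-voxel axis offsets (floored at 10⁻³ of the squared
intensity range so flat gel regions cannot blow the quotient up), and Z
normalises the per-voxel maximum component to 1.  Γ defaults to the
one-voxel 4-neighbourhood (2D) / 6-neighbourhood (3D) and p = 1, the
canonical choices of the original descriptor; the data term is the
squared mean absolute descriptor difference S² summed over the image.
The optimiser is Gauss–Newton on the descriptor channels (weighted 1/|Γ|,
a Cauchy–Schwarz upper bound of S²), sharing the pyramid and linear
solver with the mono-modal engine.  Descriptors of the warped moving
image are recomputed at every outer iteration rather than warped along.

**Shared machinery.**  Coarse-to-fine Gaussian pyramid (factor 2; 3
levels for 3D grids, 4 for 2D; a level is skipped when the coarse grid
would drop below 6 voxels).  Displacements are stored in mm so no
rescaling is needed between levels.  Every outer iteration ends with a
backtracking line search on the *true* energy: an update is only accepted
if the energy does not increase, which makes the recorded energy trace
non-increasing within each level by construction and is what the
monotonicity tests check.  Both engines are fully deterministic.

**Parameter defaults.**  α couples the data and smoothness terms after
joint intensity normalisation of the two images to [0, 1] (so it
transfers across scans).  Defaults were fixed by a grid search on the
synthetic grid phantom, trading injected-motion recovery error against
elasticity (both rigid drifts and smooth sinusoidal warps must be
recovered sub-voxel): α = 0.1 for the optical-flow engine and α = 0.7
for MIND, whose per-voxel data term is bounded by 1 and hence weaker.
Iteration caps (20/25 outer iterations per level, 15 Jacobi sweeps per
linearisation, relative-energy tolerance 10⁻⁴) were chosen so that a 3D
anchor registration converges in well under a minute on one CPU core;
all values are exposed on `OFParams`/`MINDParams` and recorded in result
metadata.

## Geometry conventions

Images carry a 4×4 voxel-index→world-mm affine; indices are 0-based and
address voxel centres.  Grid axes must be orthogonal in world space
(scaled-orthogonal affines), which keeps the mm↔index conversion a
per-axis division.  2D scans are embedded in 3D world space; the third
affine column is the slice normal scaled by the slice thickness, so a
full index |k| ≤ 0.5 means "inside the slab".  Displacement fields are
dense, one component per grid axis, in mm.  Warping is a pull-back:
`warp(J, u)(r) = J(r + u(r))`, linear interpolation by default (nearest
for masks, ties rounding toward the lower index), out-of-bounds filled
with the source minimum and flagged in a validity mask so border voxels
can be excluded from statistics rather than fabricating signal.
Composition follows the same convention:
`compose(outer, inner)(r) = inner(r) + outer(r + inner(r))`, so warping
by the composed field equals warping through both maps.

## The linked registration steps

* **RS#1** (3D anchor → reference anchor, optical flow): slow drift.  The
  field lives on the reference grid and maps reference positions to the
  current anatomy, which is directly what down-stream plan propagation
  needs (cell centre → centre + u(centre)).
* **RS#2** (thermometry magnitude dynamic → 2D reference scan, optical
  flow): residual gated respiratory motion; warping each temperature
  frame by its field aligns the series before dose accumulation.
* **RS#3** (2D scan → preceding anchor): the anchor volume is reformatted
  into the scan's geometry (plane extraction through the world-space
  affines), then refined in-plane with the MIND engine because the
  contrasts differ.  Through-plane residuals are declared out of band:
  the scans involved are gated in a narrow window and acquired back to
  back, so the generator keeps them sub-voxel as well.
* **RS#4** (2D reference scan → non-distorted EPI, optical flow): EPI
  geometric distortion, stored separately from motion.  Warping the
  distorted scan (or its dose) by the field restores the undistorted
  geometry.
* **RS#5** (sparse anatomical anchor → anchor, optical flow): the
  mono-modal silver standard used purely to validate RS#3, since by
  construction both steps should estimate the same motion.

**Up-stream dose mapping order.**  Dose accumulated in the distorted 2D
scan frame is corrected in acquisition-causal order: distortion first
(undoing the scanner-space warp), then the RS#3 residual (scan → anchor),
then painted into the 3D planning grid through the slice profile using
the RS#1 drift.  The 2D→3D painting deposits each plane through a
rectangular slab of the slice thickness (7 mm default); the coronal and
sagittal planes of one sonication are combined by voxelwise maximum
(avoiding double counting along their intersection line) and sonications
accumulate additively in CEM43.  When the non-extended protocol provides
no distortion reference, the distortion field degrades gracefully to the
identity with a logged warning.

## Thermal dose and coverage

CEM43 uses the standard Sapareto–Dean constants, R = 0.5 for T ≥ 43 °C
and R = 0.25 below, accumulated as Σ R^(43−T) · dt/60 per voxel; 240
CEM43 marks lethal dose (threshold closed at ≥).  An optional temperature
floor can clamp noise-driven dose; it is disabled by default so the
closed-form tests are exact.  Plan coverage is the percentage of the
rasterized union of the plan's cell ellipsoids that reaches lethal dose;
coverage statistics are computed on a 1 mm planning grid to keep
rasterization error small against 4 mm diameter cells.

## Evaluation metrics

Endpoint error EE(r) = ‖u_a(r) − u_b(r)‖₂ between two fields, evaluated
over a structure/organ ROI; motion magnitude sets M = {‖u(r)‖₂ : r ∈ ROI};
summaries report mean and the 5/25/50/75/95th percentiles with linear
interpolation between order statistics.  The magnitude set is defined
with the plain (non-squared) norm so summaries carry mm units.

## Synthetic phantom and what it does (not) show

The generator emulates a motorised-platform phantom experiment: a bright
gel cylinder containing two orthogonal dark grid structures (coronal and
sagittal slabs; 16 mm bar spacing, 4 mm bars, sub-voxel edge ramps so
analytic renderings stay interpolation-consistent), rigid head–foot
motion from a quasi-periodic breathing trace (sinusoid, per-cycle period
redrawn uniformly from 3–5 s, 10 mm peak-to-peak by default) plus two
5 mm step drifts injected after the 3rd and 6th of nine anchors, gated
acquisition (5 mm navigator window for thermometry, 2 mm for the
reference-type scans, window anchored at the exhale trough), an EPI-like
second contrast (monotone gamma remap, mild smoothing, independent
Gaussian noise), smooth phase-encode-directional distortions built from
low-order cosines and calibrated to exactly 5 mm mean / 6 mm max at the
structure grid points, and Gaussian hotspot temperature series (60 °C
peak, 3 mm sigma, linear heat-up and exponential decay).

Because the phantom is an analytic function of world coordinates, every
scan is rendered by sampling it at displaced/warped positions and the
injected transform is known *exactly* — for distorted scans the true
correction field is constructed first and the scan rendered through its
fixed-point inverse, so no interpolation enters the ground truth.  The
acceptance experiments therefore measure genuine recovery error, not
generator error.

Limitations of the analogue: motion is rigid (fewer degrees of freedom
than an abdominal organ; an elastic perturbation mode exists in the test
suite via injected smooth warps), noise is additive Gaussian rather than
Rician, the EPI contrast is a stylised remap rather than a sequence
simulation, and through-plane motion is kept sub-voxel by construction.
Passing tests show the estimation and propagation machinery is correct
and accurate under these conditions; they do not certify in-vivo
performance on deforming organs.

## Numerical choices and degenerate inputs

Constant (structure-free) images cannot constrain a deformation and
return the zero field with a warning flag rather than an error.
Non-finite voxels are rejected.  Registration of images on different
grids is refused (reformat first; RS#3/RS#5 do this internally).  The
distortion generator inverts (id+g) by fixed-point iteration (30 steps,
ample for the |∂g| ≪ 1 fields used).  Problem sizes in the acceptance
experiments — the 96×96×40 anchor grid, 8 sonication bundles, 8
thermometry dynamics per plane — match the emulated protocol while
keeping a full validation run in the minutes range on a single core.

## Known limitations

No diffeomorphic field inversion (composition only), no temporal
regularisation across dynamics, no spontaneous-motion detection, no
DICOM ingestion, and the respiratory model treats scans as frozen at one
gated sample rather than integrating k-space over the acceptance window.
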