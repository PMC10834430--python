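# Methods

This note records the models and algorithms behind `seg2fe`, the defaults
and why they were chosen, what the synthetic data does and does not
emulate, and the known limitations.

## Problem setting

Automatic knee-MRI segmentation produces binary voxel masks of the femur
and tibia. Their marching-cubes surfaces carry staircase roughness, speckle
artifacts and holes; meshing them directly for finite-element analysis
harms element quality and contact convergence. The toolkit replaces manual
clean-up with a statistical shape model (SSM): a population-trained prior
that, fitted to the raw surface, returns a smooth, hole-free, anatomically
plausible bone surface ready for cartilage meshing.

## Coordinate conventions

All lengths are millimetres. Voxel grids use 0-based indices with the
origin at the center of voxel (0, 0, 0), so world position =
`origin + index · spacing` — the convention of axis-aligned NIfTI affines.
Negative-step NIfTI axes are flipped on read (with the origin adjusted);
oblique grids are rejected. Meshes live in world millimetres.

## Mask ↔ surface conversion

Surfaces come from marching cubes at iso-level 0.5 on the zero-padded
binary field, keeping only the largest connected component (automatic
segmentations shed speckles). Voxelization is the exact parity test: a
voxel is foreground iff its center lies inside the closed surface, decided
by counting crossings of a vertical ray per grid column (columns are
jittered by ~0.2% of a voxel to avoid grazing marching-cubes vertices that
are aligned with voxel centers). Open meshes are rejected with the
boundary-edge count.

## Surface sampling and uniformization

Blue-noise point sets are drawn by farthest-point selection from a dense
area-uniform candidate pool (15× oversampling, seeded), which yields the
empty-disk property; uniformization is a spring relaxation that equalizes
neighbor distances (rest length = mean nearest-neighbor distance, neighbor
radius 1.3× the median), re-projecting onto the surface each step and
rejecting any step that would increase the nearest-neighbor-distance
spread. A perfectly uniform set is an exact fixed point.

## Dense correspondence

Template landmarks are chosen by *deterministic* farthest-point sampling
over the template's vertices and face centroids, then uniformized; making
the landmarks a pure function of the template geometry keeps the whole
correspondence deterministic, which matters both for reproducibility and
for model compactness (any sampling noise in the chain reappears as
spurious shape variance).

Per sample, the chain is:

1. **Coarse similarity alignment** by centroid, centroid size (RMS radius)
   and principal axes, with axis signs fixed by third-moment agreement and
   reflections forbidden.
2. **Robust pose disambiguation.** Principal axes are unstable whenever
   covariance eigenvalues are close (bones are near-degenerate this way),
   up to full axis swaps. All 24 proper octahedral rotations of the coarse
   pose are refined by a short point-to-point ICP and ranked by median
   surface distance (median, not RMS, so segmentation artifacts do not
   dominate), with the leaders re-scored against the exact surface.
3. **CPD rigid/similarity registration** (Myronenko-style EM over a
   Gaussian mixture with uniform outlier weight w = 0.1) of the template
   landmarks onto a deterministic vertex subset of the sample, followed by
   a short exact-surface ICP polish.
4. **Multiscale coherent closest-point transport.** The accumulated
   displacement field from the rigid-posed landmarks is updated by
   closest-point pulls and smoothed each step over the template's own
   k-nearest-neighbor graph with a Gaussian kernel whose width anneals
   from 8 to 1 median point spacings. Smoothing the *total* field (rather
   than the increments) redistributes tangential stretch elastically, so
   tangential coordinates are transported from the template instead of
   being re-assigned by local point density — the property that keeps a
   low-dimensional population low-dimensional after PCA. A final exact
   projection puts every landmark on the sample surface.

CPD non-rigid registration is implemented and exposed
(`registration.cpd_nonrigid`, displacement field `v = G·W`, kernel width
β = 2 and coherence weight λ = 3 in unit-RMS normalized coordinates), but
it is *not* used inside the correspondence chain: its E-step assigns
tangential positions by matching point densities, which is inconsistent
across samples — on the synthetic two-mode population it concentrates only
55–79% of the variance in two PCA modes, versus ≥ 99% for the transport
above (the analytic generative map itself reaches 99.9%).

## Shape model

Rigid-only generalized Procrustes analysis (no scale normalization —
absolute bone size carries mechanical meaning) aligns the corresponded
sets about their evolving mean; PCA of the mean-centered flattened sets
gives orthonormal modes and variances. Modes are retained to 95%
cumulative variance by default (ties kept). The template mesh is warped
onto the mean by a 3-D thin-plate spline (kernel U(r) = r, bordered
system solved in unit-normalized coordinates with one step of iterative
refinement), so every model instance can be tessellated by warping the
stored template — identical connectivity across instances.

## Model fitting (segmentation adjustment)

Active-shape style alternation: closest-point targets on the raw surface
for every model point; a regularized linear solve for the mode weights
`b` (Tikhonov weight λ_b = 1 in σ-normalized units, hard ±3σ clamp per
mode — the clamp is what fills holes and rejects artifacts, by keeping
the solution inside the plausible shape space); a closed-form similarity
pose refit on the same correspondences. Initialization uses the robust
octahedral pose search plus CPD; because mirrored pose basins on
near-symmetric bones only separate once the shape deforms, short triage
fits run from the four best distinct pose candidates and the winner is
fitted to convergence (mean point movement < 1 mm·10⁻³). Exposed knobs:
λ_b (fidelity vs plausibility), clamp width, similarity vs strict-rigid
pose, point budget.

## Evaluation metrics

Dice = 2|A∩B|/(|A|+|B|) on identical grids (IoU also reported, since the
two are often conflated in the literature); both-empty is defined as 1
with a warning. Surface distances are exact vertex-to-triangle values via
a conservatively pruned spatial query (verified against an exhaustive
search to 1e-9 mm); the Hausdorff distance is the symmetric maximum over
both directed sets and the average distance the mean of both sets
concatenated. The displaced-area fraction assigns each vertex one third
of its incident triangle area and reports the percentage of predicted
area farther than 1 mm (configurable) from the ground truth. When one
input is a mesh and the other a mask, the mesh is voxelized on the mask's
grid for the Dice computation.

## Cartilage extrusion

The contact patch is the largest edge-connected set of bone faces whose
centroids lie within 2 mm (default) of the articular surface. A regular
nu×nv node grid is laid over the patch's least-squares plane — in-plane
axes picked by minimum-area bounding rectangle, since the SVD directions
are arbitrary for isotropic patches — and projected onto the patch
surface. Extrusion sweeps each node along its area-weighted normal to the
articular surface (per-node thickness from the ray hit), splitting the
column into equal layers; five layers by default. Where the normal ray
misses (cartilage margins), the node keeps its normal direction with the
along-normal component of the nearest-point offset as thickness, floored
at 0.1 mm — skewed nearest-point columns would invert neighboring
elements. Interface nodes are the patch nodes verbatim (conforming
bone–cartilage interface); element ordering follows Abaqus C3D8 with the
bottom quad counter-clockwise about the extrusion direction. Quality is
summarized by corner scaled Jacobians (trilinear shape functions),
inversion counts, thickness and aspect ratios. INP export writes *NODE,
*ELEMENT TYPE=C3D8P and named sets (interface, articular, per-layer);
element-size presets 2/1/0.5 mm mirror common coarse/fine/very-fine
sensitivity levels. FE solving itself is out of scope.

## 1-D SPM

Two-sample pointwise t (pooled variance by default, Welch optional) over
trajectories sharing Q = 101 nodes (0–100% stance). Field smoothness is
estimated from the unit-variance-normalized residual gradients,
FWHM = sqrt(4 ln 2)/RMS-gradient. The critical threshold solves
`P(max |t| > u) ≈ alpha` using the expected-Euler-characteristic
approximation for 1-D t-fields — survival term plus resel count
(Q−1)/FWHM times the EC density — by bisection to 1e-6; two-tailed
inference splits α across tails (one-tailed available). In the
infinitely-smooth limit the threshold reduces to the ordinary two-tailed
Student-t quantile. Validation is by Monte-Carlo simulation of smooth
Gaussian null fields: the empirical null rejection rate at α = 0.05 falls
within [0.03, 0.07], and the analytic threshold matches the simulated
95th percentile of max |t| within Monte-Carlo error across a grid of
(df, FWHM) settings.

## Synthetic data

The shape family is a distal-femur-like implicit surface: two ellipsoidal
condyles (the lateral one enlarged by a fixed 1.15 factor) and an offset
cylindrical shaft, blended by a smooth union (log-sum-exp, 3 mm radius)
and meshed by marching cubes at 1.2 mm pitch. The fixed
medial/lateral asymmetry gives the family well-defined principal axes, as
a real distal femur has. Active latent modes and their defaults: condyle
width 11 ± 1.0 mm and condyle separation 24 ± 2.0 mm (≈ 8–9% coefficients
of variation, a plausible anatomical spread); the shaft radius (9 mm) is
frozen, so the population is exactly two-dimensional. Mask degradation
voxelizes the truth at 0.5 mm isotropic (an MRI-like anisotropic
0.36 × 0.36 × 0.7 mm preset is provided), adds surface noise by
re-voxelizing a vertex-jittered copy (σ = 0.3 mm), carves spherical holes
(3 of radius 2 mm) at random surface points, and flips boundary voxels
with probability 0.02. Trajectory ensembles are Gaussian white noise
convolved with a Gaussian kernel of chosen FWHM, normalized to unit
process variance (padding keeps the process stationary), with a mean
shift as the group effect.

What this emulates: the geometry-level failure modes of automatic
segmentation and the smoothness structure of gait waveforms. What it does
not: MRI intensities, real anatomical shape statistics (the family is a
controllable stand-in, not an atlas), segmentation-network error
correlations, or FE mechanics. Passing tests therefore demonstrate the
correctness and calibration of the algorithms, not clinical accuracy.

## Problem sizes and numerical choices

The test suite and the acceptance script run the study at 30 training
shapes with 600 landmarks; the library default point budget is 5000.
TPS systems are solved via LU with one iterative-refinement step;
CPD EM stops when σ² changes by < 1e-6 relative; the transport runs 6
iterations per kernel level at step 0.8. Degenerate inputs are rejected
with specific errors (empty masks, open meshes for voxelization,
coplanar landmark sets, coincident TPS control points, oversized
degradation holes).

## Known limitations

- Correspondence quality degrades for populations whose extreme draws
  (±3σ) approach degenerate geometry — e.g., condyle separation below the
  combined condyle width, where the two condyles merge into one blob. The
  two-mode variance share can then drop to 80–90%; the generative map
  itself stays two-dimensional, so this is a limitation of geometry-driven
  registration, not of the model.
- The two-condyle anatomy is nearly mirror-symmetric; pose disambiguation
  relies on the fixed medial/lateral asymmetry and on deformable triage.
  Bones with genuinely symmetric geometry would remain ambiguous.
- The mesh resampler targets vertex count and fidelity, not guaranteed
  minimum triangle angles.
- Voxelization assumes axis-aligned grids; oblique MRI geometries must be
  resampled upstream.
- SPM inference assumes stationary smoothness along the domain; strongly
  non-stationary trajectories would need a non-stationary resel count.
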