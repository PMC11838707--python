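# Methods

This note records the model, the numerical choices, and the deliberate
design decisions behind `seqseg`, in enough detail that a maintainer can
tell which behaviours are contractual and which are free parameters.

## Coordinate and grid conventions

All geometry is in world millimetres.  Volumes are axis-aligned grids with
per-axis spacing and an origin; a voxel's world position is
`origin + index·spacing` (node convention), so an axis of `n` voxels spans
`(n−1)·spacing`.  Oblique direction matrices are rejected at load time:
the tracing geometry (cube extraction, cap planes) is only well defined on
axis-aligned data, and supporting rotations would buy nothing for the
method itself.  Subvolumes are physical cubes `[c−L/2, c+L/2]³` resampled
onto a fixed patch grid (default 64³, the usual network input size);
partial cubes are an *error*, never zero-padded, because boundary overrun
is the tracer's natural stop signal.

## Preprocessing

MR-style volumes are z-scored with their own mean/sd; CT-style volumes are
clipped to configured bounds (conventionally the 0.5/99.5 intensity
percentiles of a training corpus) and z-scored with *fixed* foreground
statistics supplied at inference.  Image resampling uses 3rd-order
splines; label resampling linearly interpolates one-hot channels and takes
the per-voxel argmax, which keeps labels strictly binary.  Note that
spline boundary handling leaks a geometrically decaying error inward from
the volume faces, so "splines reproduce linear ramps" holds only in the
deep interior (the error decays by ≈0.27 per voxel of depth); the tests
check the reproduction there.

## Patch sampling and loss

Training patches for a learned backend are cubes of side `L = α·R`
(`α ~ N(5, 1)`, truncated below at 2 by redrawing so a cube always
contains the lumen) centered at `c = C + β·R·w` (`β ~ N(0, 0.8)` — 0.8 is
the *variance*), where `w = (a·u + b·v)/‖a·u + b·v‖` with
`a, b ~ U[−1, 1]` and `(u, v)` an orthonormal basis of the plane
perpendicular to the centerline tangent.  Sample points are spaced at half
a local radius of arclength along each branch; the multiplicity per point
is a free parameter, so dataset sizes are configuration-dependent.

The loss is `(1 − Dice) + BCE` on soft values: the Dice term uses the
voxelwise product as intersection, BCE clamps predictions to
`[1e−7, 1 − 1e−7]`.  The sum of a *score* and a *log-likelihood* only
makes sense as a minimization target with this sign convention, which is
also the standard Dice+CE compound used throughout patch-based medical
segmentation.

## Local geometry

Marching cubes runs at level 0.5 on the probability patch.  The surface is
clipped by the six cube planes inset by one patch voxel — surfaces touching
the array border produce degenerate geometry, and the inset yields clean
boundary loops.  Each open loop becomes a cap with center (loop mean) and
radius (mean vertex distance to center); caps are sorted by (face id,
centroid) so source/target ties break deterministically.  The cap nearest
the previous stepping point is the source; at a fresh seed the fictitious
previous point `p₀ − r₀·t₀` makes the upstream cap the source.

Centerlines are computed on the *grid* (binarized at 0.5), not on the
mesh: the governing equation `|∇T|F = 1` is a grid PDE, and the mesh is
only needed to locate caps.  The speed is the Euclidean distance transform
(first power) clamped below at `0.1·min(spacing)` to avoid zero speed at
the wall.  The eikonal solver is a first-order Godunov upwind
discretization iterated with damped Jacobi sweeps restricted to the
foreground; it converges in roughly as many sweeps as the longest geodesic
is voxels long and is bitwise deterministic.  Against a 26-neighborhood
Dijkstra oracle the arrival times agree to within 15% along extracted
paths away from the source voxel; close to the source the two first-order
discretizations differ by construction and a relative comparison is not
meaningful.  Paths are extracted by gradient descent on trilinearly
interpolated `∇T` with step `0.5·min(spacing)`, termination within one
voxel of the source, a 10⁵-step budget, and a stall detector (arrival time
must keep decreasing).  A light 5-point moving average removes grid
zigzag.  Per-point radii are the interpolated distance-to-boundary values.
Target paths sharing a prefix (within one voxel) are merged; the junction
is the last shared point, which is how bifurcations are represented
implicitly.  Stepping points sit at 80% of each source-to-target path's
arclength, with central-difference tangents.

## The tracing loop

The cube side follows `L = 5·(rᵢ + rᵢ₋₁)/2`, averaging with the previous
radius to damp underestimation.  If the predicted fill fraction
`γ = mean(Y_p ≥ 0.5)` reaches the cutoff `γ* = 0.2`, the side is enlarged
*compounding* by 10% per re-segmentation until `L/L₀ > 1.3`.  (A
non-compounding enlargement cannot make progress: it would re-evaluate the
same cube forever.  γ* itself is a free parameter; a 5R cube around a
cylinder of radius R has fill fraction π/25 ≈ 0.13, so 0.2 flags an
oversized vessel.)  Failures trigger a chance step `p ← p + r·t`; the
counter measures *consecutive* failures (reset on every accepted step,
since difficult regions recur independently) and allows three chances.

The bifurcation queue is re-sorted by radius at every pop — the cheapest
policy that always prioritizes the largest untraced vessel.  Because
outlets are detected locally, the same junction can be seen from several
consecutive cubes; a candidate outlet within `2·max(r)` of an existing
queue entry or of a stepping point of a *different* branch is dropped as a
duplicate (same-branch points are exempt so forward progress is never
blocked; a popped entry is removed from the set so its own branch can
start).  The periodic retracing check (every 5 accepted steps) measures
the fraction of the current prediction's foreground voxels whose global
read-out — excluding the current branch's last 3 contributions, the
"buffer" — is already above threshold; above 0.8 the branch is declared
retraced.  Normalizing by the *foreground* rather than the whole cube is
what makes the threshold meaningful: a vessel fills only ~13% of its cube,
so a whole-cube fraction could never approach 0.8.

Stop criteria: image boundary (an out-of-bounds cube), low resolution
(cube spanning fewer than 8 native voxels per axis), radius below
`R_min = 0.5 mm`, `N_max = 500` total steps, `NB_max = 15` branches.

## Global assembly

Every accepted prediction is resampled linearly onto the covered global
voxels (one canonical frame, no compounded interpolation) and accumulated
with Gaussian weights `w = exp(−‖p − c‖²/(2σ²))`, `σ = L/4`.  A cube-edge
midpoint lies at `L/√2 = 2√2·σ`, giving `e⁻⁴ ≈ 0.018 ≈ 0.02`; face
centers lie at `2σ` (`e⁻² ≈ 0.135`).  The read-out is the plain weighted
mean `Σw·s / Σw` — adding a `1/N` prefactor on an already weight-normalized
sum would shrink every multiply-covered voxel toward zero and break
idempotence, so the weighted mean is the only self-consistent reading.
Finalization thresholds at `t = 0.5` (a voxel exactly at the threshold is
vessel), keeps the largest 26-connected component (the most permissive
connectivity, so thin vessels stay attached), optionally after upsampling
to a configured spacing, and meshes + smooths the mask.  Smoothing is
Taubin λ|μ low-pass filtering with `1/λ + 1/μ = passband` (λ = 0.5,
10 iterations, passband 0.01): a vertex-moving filter that preserves
vertex count and watertightness, chosen as the classical windowed-sinc
style low-pass for removing voxel staircase artifacts.

## Metrics

Dice is voxelwise; both-empty scores 0 by convention.  Hausdorff is
computed on *boundary* voxels (the surfaces, not filled volumes) and
reported in pixel units by default.  Centerline overlap discretizes the
reference tree at quarter-voxel intervals and integrates the binary mask
along it by the trapezoid rule.  The six-radius evaluation mask labels
every voxel within six times the *nearest* centerline sample's local
radius — radii vary along a tree, so the nearest-point rule is the only
local reading — and is applied to both masks before scoring so that
unannotated vessels do not count against a prediction.  The Wilcoxon
signed-rank comparison of score sets is a thin wrapper over
`scipy.stats.wilcoxon`.

## The phantom generator

The phantom emulates a contrast-filled vessel tree: a union of balls swept
along branch polylines (a capsule chain) with linearly tapering radii,
rendered at lumen intensity 100 over background 0 with additive white
Gaussian noise (default sd 10, a contrast-to-noise ratio of 10 —
representative of decent CT angiography).  Children attach at their
parent's endpoint (Y junctions) with radii scaled by a decay ratio and
symmetric branching angles drawn from a configured range.  Corruption
boxes overwrite the *image* (never the label) with structureless noise to
exercise the chance mechanism; the oracle backend additionally goes blind
(all-zero output) when a patch center falls inside a box or corruption
covers more than half the patch.

What the phantom does *not* model: partial-volume effects, intensity
inhomogeneity, modality-specific artifacts, stenoses/aneurysms, curved or
touching vessels.  Passing phantom tests therefore demonstrates the
correctness of the tracing, geometry and assembly machinery — not the
segmentation difficulty of real angiography, which lives entirely in the
plugged-in backend.

## Problem sizes used in the tests

The end-to-end checks run on 128³ voxel phantoms at 1 mm spacing (tube
radius 4 mm, Y-junction children 2.8 mm), a 240×96×96 grid at 0.25 mm for
the tapering-tube minimum-radius check, and a 160³ four-generation tree
for the branch-budget check; these sizes keep a full trace in the tens of
seconds while leaving every mechanism (enlargement, chances, queueing,
retracing, all stop criteria) exercised.

## Known limitations

* The tracer assumes roughly tubular topology; loops are only handled by
  the retracing check, not represented in the output tree.
* Cap radius (mean loop-vertex distance) overestimates the lumen radius
  for oblique cuts; the centerline's distance-to-boundary estimate is the
  one used for stepping and sizing.
* The duplicate-outlet suppression radius (2× the larger radius) is a
  heuristic; extremely close genuine bifurcations (closer than two radii)
  could be suppressed as duplicates.
* `is_retraced` needs the current prediction, so the check runs on
  accepted steps only; a branch that fails continuously is bounded by the
  chance budget instead.
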