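# seqseg

Sequential vascular segmentation: build a connected 3D vessel model from a
single seed point by stitching together many small, locally segmented
subvolumes.

## The problem

Global segmentation networks applied to whole CT/MR angiography volumes
often fragment thin vessels and leak into neighbouring structures, and
their output is not guaranteed to be a single connected, meshable surface
— which is what blood-flow simulation needs as a computational domain.
This package implements the alternative strategy of *tracking* the
vasculature: starting from one user-supplied seed (a point, a direction
and a rough radius, placed in the largest artery of interest), the tracer

1. extracts a cubic subvolume of side `L = 5·(rᵢ + rᵢ₋₁)/2` around the
   current point, enlarging it by 10% steps (up to 30%) while the
   predicted vessel fills more than a cutoff fraction γ* of the cube;
2. segments the cube with a pluggable local backend
   `Y_p = f(X | θ) ∈ [0,1]`;
3. runs marching cubes on the probability map, clips the surface with the
   cube faces, and classifies each resulting truncation boundary ("cap")
   as the **source** (nearest to the previous stepping point) or a
   **target**;
4. computes centerlines by solving the eikonal equation `|∇T| F = 1` on
   the binarized cube with speed `F` proportional to the
   distance-to-boundary map, then descending `∇T` from each target back
   to the source; the local radius is the distance-to-boundary value
   along the path;
5. steps to the point 80% of the way along the largest-radius path, and
   queues every other outlet as a bifurcation to revisit later (queue
   sorted by radius, largest first);
6. accumulates the local prediction into a global grid with Gaussian
   weights `w = exp(−‖p − c‖²/2σ²)`, `σ = L/4`.

Local failures (no surface, fewer than two outlets, centerline failure)
consume up to three consecutive "chances" — blind steps of one radius in
the current direction — before the branch is abandoned, which lets the
tracer cross locally corrupted image regions.  Tracing stops at the image
boundary, at low subvolume resolution, below a minimum radius
(`R_min = 0.5 mm`), or at configurable step/branch budgets
(`N_max = 500`, `NB_max = 15`).  The final global probability map is
thresholded at `t = 0.5`, reduced to its largest connected component, and
meshed + low-pass smoothed (10 iterations, passband 0.01) into a
simulation-ready surface.

Because trained network weights are deliberately out of scope, the package
ships two desk-scale backends — a ground-truth oracle and a smoothed
intensity-threshold segmenter — plus a `phantom` module that generates
synthetic tubular trees (image, label, centerline-with-radius) to exercise
every part of the pipeline.  A learned model plugs in as any object with a
`predict(patch) -> ProbabilityVolume` method.

Evaluation follows the standard trio: Dice `2|X∩Y|/(|X|+|Y|)`, symmetric
surface Hausdorff distance, and centerline overlap `∫_Ct Y dx / ∫_Ct dx`,
optionally restricted to the voxels within six local radii of the
reference centerline.

## A worked example

`examples/trace_bifurcation.py` builds a Y-shaped phantom (parent radius
4 mm splitting into two 2.8 mm children), traces it from one seed with the
oracle backend and prints:

```
bifurcations queued:  1
branches traced:      2
branch terminations:  [(0, 'chances_exhausted'), (1, 'chances_exhausted')]
Dice vs ground truth: 0.988
centerline overlap:   0.997
```

The junction is detected exactly once (one queue entry); the first traced
branch runs through the parent into one child, the queued entry covers the
other child; both terminate by exhausting chances at the rounded vessel
tips.  Dice is computed on the assembled global mask against the phantom
label, and centerline overlap of 0.997 means virtually the whole reference
tree lies inside the segmentation.  See `examples/` for single-tube
tracing, training-patch sampling and metric scoring, each runnable as
`python examples/<name>.py`.

The same pipeline is available from a shell:

```sh
seqseg phantom --kind y_bifurcation --out work/phantom
seqseg trace --image work/phantom/image.nii.gz --seed 12,64,64 \
             --direction 1,0,0 --radius 4 --out work/trace
seqseg eval --pred work/trace/segmentation.nii.gz \
            --truth work/phantom/label.nii.gz \
            --centerline work/phantom/centerline.json --mask-six-radius
```

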