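"""Trace a Y-shaped vessel: bifurcation detection and the branch queue.

The parent vessel splits into two children.  While tracing the parent the
tracer sees three truncation boundaries in one subvolume, follows the
larger outlet, and stores the other as a queued bifurcation; the queue is
revisited once the first branch terminates.  Expect exactly one queue
entry and full coverage of both children.
"""

from seqseg import (
    OracleSegmenter,
    PhantomConfig,
    TracerConfig,
    centerline_overlap,
    dice,
    generate_tree,
    run_trace,
    voxelize,
)

tree = generate_tree("y_bifurcation", start=(12, 64, 64), direction=(1, 0, 0),
                     length=50, radius=4, child_ratio=0.7, length_ratio=0.8,
                     branch_angle_deg=(35, 40), rng=1)
image, label, truth_centerline = voxelize(
    tree, PhantomConfig(grid_shape=(128, 128, 128), noise_sd=0)
)

result = run_trace(image, ((12, 64, 64), (1, 0, 0), 4.0),
                   OracleSegmenter(label), TracerConfig())
mask, _ = result.accumulator.finalize()

print(f"bifurcations queued:  {result.queue_entries_created}")
print(f"branches traced:      {result.branches_traced}")
print(f"branch terminations:  {result.termination_reasons}")
print(f"Dice vs ground truth: {dice(mask, label):.3f}")
print(f"centerline overlap:   {centerline_overlap(mask, truth_centerline):.3f}")
# overlap is computed over the *whole* reference tree, so a value >= 0.9
# means the parent and both children were all captured.
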