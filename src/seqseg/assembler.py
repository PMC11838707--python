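"""Global assembly of overlapping local predictions.

Each local prediction contributes to the global grid through a Gaussian
weight map centered on its cube, ``w = exp(-||p - c||^2 / (2 sigma^2))``
with ``sigma = L/4``, so voxels near a cube center dominate voxels near
its border (a cube-edge midpoint, at distance ``L/sqrt(2)``, gets weight
``exp(-4) ~ 0.02``).  The global read-out is the weighted mean of all
contributions per voxel; it is finally thresholded, reduced to the largest
connected component, and meshed + smoothed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from .errors import EmptySegmentation, GridMismatch
from .volume import ImageVolume, LabelVolume, ProbabilityVolume, SubvolumeSpec, resample

__all__ = [
    "AssemblerConfig",
    "AssemblyAccumulator",
    "weight_map",
    "smooth_mesh",
]


@dataclass(frozen=True)
class AssemblerConfig:
    """Final-segmentation settings.

    ``threshold`` binarizes the weighted-mean probability (a voxel exactly
    at the threshold counts as vessel).  ``smoothing_iterations`` and
    ``passband`` control the low-pass mesh smoothing.  ``upsample_spacing``
    optionally resamples the probability grid before thresholding.
    """

    threshold: float = 0.5
    smoothing_iterations: int = 10
    passband: float = 0.01
    upsample_spacing: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must be in (0, 1)")


def weight_map(spec: SubvolumeSpec) -> np.ndarray:
    """Gaussian weights on the patch grid, sigma = L/4, 1.0 at the center."""
    sigma = spec.sidelength / 4.0
    axes = [
        spec.low[a] + np.arange(spec.grid_shape[a]) * spec.patch_spacing[a]
        for a in range(3)
    ]
    d2 = (
        ((axes[0] - spec.center[0]) ** 2)[:, None, None]
        + ((axes[1] - spec.center[1]) ** 2)[None, :, None]
        + ((axes[2] - spec.center[2]) ** 2)[None, None, :]
    )
    return np.exp(-d2 / (2.0 * sigma * sigma))


class AssemblyAccumulator:
    """Running weighted-sum / weight-sum grids over the global image."""

    def __init__(self, reference: ImageVolume):
        self.spacing = reference.spacing.copy()
        self.origin = reference.origin.copy()
        self.shape = reference.shape
        self.weighted_sum = np.zeros(self.shape)
        self.weight_sum = np.zeros(self.shape)
        self.contribution_count = np.zeros(self.shape, dtype=np.int32)

    def _covered_slices(self, spec: SubvolumeSpec) -> tuple[slice, ...]:
        world_max = self.origin + (np.array(self.shape) - 1) * self.spacing
        if np.any(spec.low < self.origin - 1e-6) or np.any(spec.high > world_max + 1e-6):
            raise GridMismatch("subvolume cube exceeds the global grid")
        lo = np.ceil((spec.low - self.origin) / self.spacing - 1e-9).astype(int)
        hi = np.floor((spec.high - self.origin) / self.spacing + 1e-9).astype(int)
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, np.array(self.shape) - 1)
        return tuple(slice(l, h + 1) for l, h in zip(lo, hi))

    def contribution(
        self, prediction: ProbabilityVolume, spec: SubvolumeSpec
    ) -> tuple[tuple[slice, ...], np.ndarray, np.ndarray]:
        """(global slices, weights, resampled prediction) for one patch."""
        sl = self._covered_slices(spec)
        axes = [
            self.origin[a] + np.arange(sl[a].start, sl[a].stop) * self.spacing[a]
            for a in range(3)
        ]
        grids = np.meshgrid(*axes, indexing="ij")
        # sample the patch prediction at the covered global voxel centers
        coords = np.stack(
            [(grids[a] - prediction.origin[a]) / prediction.spacing[a] for a in range(3)]
        )
        for a in range(3):
            np.clip(coords[a], 0, prediction.shape[a] - 1, out=coords[a])
        values = ndimage.map_coordinates(
            np.asarray(prediction.data, dtype=float), coords, order=1, mode="nearest"
        )
        sigma = spec.sidelength / 4.0
        d2 = sum((grids[a] - spec.center[a]) ** 2 for a in range(3))
        weights = np.exp(-d2 / (2.0 * sigma * sigma))
        return sl, weights, values

    def accumulate(self, prediction: ProbabilityVolume, spec: SubvolumeSpec) -> None:
        """Add one local prediction (weighted) to the global grids."""
        sl, w, s = self.contribution(prediction, spec)
        self.weighted_sum[sl] += w * s
        self.weight_sum[sl] += w
        self.contribution_count[sl] += 1

    def read_out(
        self,
        exclude: list[tuple[tuple[slice, ...], np.ndarray, np.ndarray]] | None = None,
    ) -> ProbabilityVolume:
        """Weighted-mean probability; uncovered voxels read 0.

        ``exclude`` subtracts specific stored contributions first — used by
        the tracer's retracing check to ignore the current branch's most
        recent steps.
        """
        ws = self.weighted_sum
        w = self.weight_sum
        if exclude:
            ws = ws.copy()
            w = w.copy()
            for sl, ew, es in exclude:
                ws[sl] -= ew * es
                w[sl] -= ew
            w = np.maximum(w, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(w > 1e-12, ws / np.where(w > 1e-12, w, 1.0), 0.0)
        return ProbabilityVolume(np.clip(out, 0.0, 1.0), self.spacing.copy(), self.origin.copy())

    def finalize(
        self, config: AssemblerConfig | None = None
    ) -> tuple[LabelVolume, trimesh.Trimesh]:
        """Threshold, keep the largest connected body, mesh and smooth it."""
        config = config or AssemblerConfig()
        prob = self.read_out()
        if config.upsample_spacing is not None:
            prob_img = resample(
                ImageVolume(prob.data, prob.spacing, prob.origin),
                config.upsample_spacing,
                kind="image",
            )
            prob = ProbabilityVolume(
                np.clip(prob_img.data, 0.0, 1.0), prob_img.spacing, prob_img.origin
            )
        mask = (prob.data >= config.threshold).astype(np.uint8)
        if not mask.any():
            raise EmptySegmentation("no voxel reaches the assembly threshold")
        labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=np.uint8))
        if n > 1:
            sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
            mask = (labels == (1 + int(np.argmax(sizes)))).astype(np.uint8)
        label_vol = LabelVolume(mask, prob.spacing.copy(), prob.origin.copy())
        verts, faces, _, _ = measure.marching_cubes(
            mask.astype(float), level=0.5, spacing=tuple(prob.spacing)
        )
        mesh = trimesh.Trimesh(vertices=verts + prob.origin[None, :], faces=faces, process=False)
        mesh = smooth_mesh(mesh, config.smoothing_iterations, config.passband)
        return label_vol, mesh


def smooth_mesh(
    mesh: trimesh.Trimesh, iterations: int = 10, passband: float = 0.01
) -> trimesh.Trimesh:
    """Low-pass vertex smoothing that removes voxel staircase artifacts.

    Taubin lambda/mu smoothing with the pass-band frequency ``k_pb``
    satisfying ``1/lambda + 1/mu = k_pb``: alternating shrink/inflate steps
    act as a low-pass filter on surface detail without net shrinkage, and
    the vertex count is preserved.
    """
    if len(mesh.vertices) == 0 or iterations <= 0:
        return mesh
    lamb = 0.5
    mu = 1.0 / (passband - 1.0 / lamb)  # negative for passband < 2
    out = mesh.copy()
    trimesh.smoothing.filter_taubin(out, lamb=lamb, nu=-mu, iterations=iterations)
    return out
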