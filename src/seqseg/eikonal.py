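"""Upwind eikonal solver on a masked, anisotropic voxel grid.

Solves ``|grad T(x)| * F(x) = 1`` for the arrival time ``T`` of a wave
front released at one or more source voxels, restricted to a foreground
mask.  The discretization is the standard first-order Godunov upwind
scheme; the fixed point is reached by damped Jacobi sweeps (every voxel
re-solved from its current neighbor values each sweep), which converges in
roughly as many sweeps as the longest geodesic is voxels long and is
bitwise deterministic.

Used with a speed proportional to the distance-to-boundary map, the
resulting ``T`` grows fastest along the vessel center, so gradient descent
on ``T`` from a distal point recovers a centered path.
"""

from __future__ import annotations

import numpy as np

__all__ = ["eikonal_solve"]

_INF = np.inf


def _neighbor_ids(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Compact ids of masked voxels and their 6-neighbors (-1 when absent)."""
    compact = -np.ones(mask.shape, dtype=np.int64)
    compact[mask] = np.arange(int(mask.sum()))
    idx = np.argwhere(mask)
    nbrs = np.empty((3, 2, len(idx)), dtype=np.int64)
    for a in range(3):
        for k, step in enumerate((+1, -1)):
            shifted = idx.copy()
            shifted[:, a] += step
            valid = (shifted[:, a] >= 0) & (shifted[:, a] < mask.shape[a])
            ids = -np.ones(len(idx), dtype=np.int64)
            ids[valid] = compact[tuple(shifted[valid].T)]
            nbrs[a, k] = ids
    return compact, nbrs


def _upwind_solve(nmins: np.ndarray, hs: np.ndarray, cost: np.ndarray) -> np.ndarray:
    """Solve the per-voxel upwind quadratic given axis neighbor minima.

    ``nmins``: (3, n) neighbor minimum per axis (inf when none);
    ``hs``: (3,) spacings; ``cost``: (n,) = 1/F.  Returns candidate T.
    """
    n = nmins.shape[1]
    order = np.argsort(nmins, axis=0, kind="stable")
    a = np.take_along_axis(nmins, order, axis=0)
    h = hs[:, None][order, np.zeros((3, n), dtype=np.int64)]
    w = 1.0 / (h * h)

    # one-term solution
    sol = a[0] + cost * h[0]

    # two-term solution where it is consistent (T >= a2)
    use2 = np.isfinite(a[1]) & (sol > a[1])
    if np.any(use2):
        w1, w2 = w[0][use2], w[1][use2]
        a1, a2 = a[0][use2], a[1][use2]
        A = w1 + w2
        B = -2.0 * (w1 * a1 + w2 * a2)
        C = w1 * a1 * a1 + w2 * a2 * a2 - cost[use2] ** 2
        disc = B * B - 4.0 * A * C
        ok = disc >= 0
        t2 = np.where(ok, (-B + np.sqrt(np.maximum(disc, 0.0))) / (2.0 * A), np.inf)
        sub = sol[use2]
        sub = np.where(ok & (t2 >= a2), t2, sub)
        sol[use2] = sub

    # three-term solution where consistent (T >= a3)
    use3 = np.isfinite(a[2]) & (sol > a[2])
    if np.any(use3):
        w1, w2, w3 = w[0][use3], w[1][use3], w[2][use3]
        a1, a2, a3 = a[0][use3], a[1][use3], a[2][use3]
        A = w1 + w2 + w3
        B = -2.0 * (w1 * a1 + w2 * a2 + w3 * a3)
        C = w1 * a1 * a1 + w2 * a2 * a2 + w3 * a3 * a3 - cost[use3] ** 2
        disc = B * B - 4.0 * A * C
        ok = disc >= 0
        t3 = np.where(ok, (-B + np.sqrt(np.maximum(disc, 0.0))) / (2.0 * A), np.inf)
        sub = sol[use3]
        sub = np.where(ok & (t3 >= a3), t3, sub)
        sol[use3] = sub
    return sol


def eikonal_solve(
    speed: np.ndarray,
    mask: np.ndarray,
    sources: np.ndarray,
    spacing,
    tol: float = 1e-6,
    max_sweeps: int | None = None,
) -> np.ndarray:
    """Arrival-time grid ``T`` with ``T = 0`` at the source voxels.

    Parameters
    ----------
    speed
        Positive wave speed per voxel (only read inside ``mask``).
    mask
        Boolean foreground; ``T`` is ``inf`` outside.
    sources
        (k, 3) integer voxel indices, must lie in the mask.
    spacing
        Per-axis voxel size (mm).
    tol
        Convergence threshold on the largest per-sweep change, in time
        units of ``min(spacing) / max(speed)``.
    max_sweeps
        Sweep budget; defaults to ``2 * (nx + ny + nz) + 100``.
    """
    mask = np.asarray(mask, dtype=bool)
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    sources = np.atleast_2d(np.asarray(sources, dtype=np.int64))
    if not np.all(mask[tuple(sources.T)]):
        raise ValueError("all source voxels must lie inside the mask")

    compact, nbrs = _neighbor_ids(mask)
    n = int(mask.sum())
    speed_flat = np.asarray(speed, dtype=float)[mask]
    if np.any(speed_flat <= 0):
        raise ValueError("speed must be strictly positive inside the mask")
    cost = 1.0 / speed_flat

    T = np.full(n, _INF)
    src_ids = compact[tuple(sources.T)]
    T[src_ids] = 0.0
    frozen = np.zeros(n, dtype=bool)
    frozen[src_ids] = True

    if max_sweeps is None:
        max_sweeps = 2 * int(sum(mask.shape)) + 100
    abs_tol = tol * float(spacing.min()) * float(cost.min())

    pad = np.array([_INF])
    for _ in range(max_sweeps):
        nmins = np.empty((3, n))
        for a in range(3):
            plus = np.concatenate([T, pad])[nbrs[a, 0]]
            minus = np.concatenate([T, pad])[nbrs[a, 1]]
            nmins[a] = np.minimum(plus, minus)
        candidate = _upwind_solve(nmins, spacing, cost)
        candidate[frozen] = 0.0
        new_T = np.minimum(T, candidate)
        finite = np.isfinite(new_T) & np.isfinite(T)
        delta = 0.0
        if np.any(finite):
            delta = float(np.max(np.abs(new_T[finite] - T[finite])))
        newly = np.isfinite(new_T) & ~np.isfinite(T)
        T = new_T
        if not np.any(newly) and delta <= abs_tol:
            break

    out = np.full(mask.shape, _INF)
    out[mask] = T
    return out
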