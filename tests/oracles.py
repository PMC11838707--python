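"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's own code paths (and the library
shortcuts it uses) so they can serve as oracles: plain Dijkstra on the
26-neighborhood graph, all-pairs Hausdorff, and nearest-neighbor patch
re-extraction.
"""

from __future__ import annotations

import heapq
import itertools

import numpy as np


def dijkstra_times(speed: np.ndarray, mask: np.ndarray, source, spacing) -> np.ndarray:
    """Shortest travel time on the 26-neighborhood voxel graph.

    Edge time = edge length / mean endpoint speed.
    """
    spacing = np.asarray(spacing, dtype=float)
    shape = mask.shape
    T = np.full(shape, np.inf)
    T[tuple(source)] = 0.0
    heap = [(0.0, tuple(int(c) for c in source))]
    offsets = [o for o in itertools.product((-1, 0, 1), repeat=3) if o != (0, 0, 0)]
    lengths = {o: float(np.linalg.norm(np.asarray(o) * spacing)) for o in offsets}
    visited = set()
    while heap:
        t, u = heapq.heappop(heap)
        if u in visited:
            continue
        visited.add(u)
        for o in offsets:
            v = (u[0] + o[0], u[1] + o[1], u[2] + o[2])
            if any(c < 0 or c >= s for c, s in zip(v, shape)):
                continue
            if not mask[v]:
                continue
            tv = t + lengths[o] / (0.5 * (speed[u] + speed[v]))
            if tv < T[v]:
                T[v] = tv
                heapq.heappush(heap, (tv, v))
    return T


def brute_hausdorff(points_a: np.ndarray, points_b: np.ndarray) -> float:
    """All-pairs symmetric Hausdorff distance between two point sets."""
    a = np.asarray(points_a, dtype=float)
    b = np.asarray(points_b, dtype=float)
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


def boundary_voxels_bruteforce(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with a background (or out-of-grid) 6-neighbor."""
    out = []
    for idx in np.argwhere(mask):
        for a in range(3):
            for step in (-1, 1):
                n = idx.copy()
                n[a] += step
                if np.any(n < 0) or np.any(n >= np.array(mask.shape)):
                    continue
                if not mask[tuple(n)]:
                    out.append(idx)
                    break
            else:
                continue
            break
    if not out:
        return np.empty((0, 3), dtype=int)
    return np.asarray(out)


def trilinear_label_patch(label, spec) -> np.ndarray:
    """Hand-rolled re-extraction of a binary label over a cube.

    Trilinear interpolation of the foreground channel written out loop by
    loop, thresholded at 0.5 (the one-hot + argmax rule for two classes).
    """
    g = spec.grid_shape
    low = spec.low
    ps = spec.patch_spacing
    data = np.asarray(label.data, dtype=float)
    shape = np.array(label.shape)
    out = np.zeros(g, dtype=np.uint8)
    for i in range(g[0]):
        for j in range(g[1]):
            for k in range(g[2]):
                world = low + np.array([i, j, k]) * ps
                f = np.clip((world - label.origin) / label.spacing, 0, shape - 1)
                i0 = np.minimum(np.floor(f).astype(int), shape - 2)
                t = f - i0
                val = 0.0
                for di in (0, 1):
                    for dj in (0, 1):
                        for dk in (0, 1):
                            w = (
                                (t[0] if di else 1 - t[0])
                                * (t[1] if dj else 1 - t[1])
                                * (t[2] if dk else 1 - t[2])
                            )
                            val += w * data[i0[0] + di, i0[1] + dj, i0[2] + dk]
                out[i, j, k] = 1 if val >= 0.5 else 0
    return out
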