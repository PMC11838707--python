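"""Local vessel geometry: surface, truncation caps, centerlines, stepping.

Pipeline per subvolume:

1. :func:`surface_from_probability` — marching-cubes isosurface of the
   probability patch.
2. :func:`clip_and_caps` — cut the surface with the (slightly inset) cube
   faces; every resulting open boundary loop is a truncation boundary
   ("cap") where the vessel crosses a face.
3. :func:`assign_roles` — the cap nearest the previous stepping point is
   the source (inlet); all others are targets (outlets).
4. :func:`compute_centerline` — wave propagation (eikonal) from the source
   over the binarized patch, with speed proportional to the
   distance-to-boundary map, then gradient descent from each target back
   to the source; per-point radius is the distance-to-boundary value.
5. :func:`stepping_points` — the point 80% of the way along each
   source-to-target path, with local tangent and radius.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import trimesh
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure

from .centerline import Branch, CenterlineTree
from .eikonal import eikonal_solve
from .errors import CenterlineFailure, InsufficientOutlets, NoSurface
from .volume import ImageVolume, LabelVolume, ProbabilityVolume, SubvolumeSpec

__all__ = [
    "CapBoundary",
    "surface_from_probability",
    "clip_and_caps",
    "assign_roles",
    "compute_centerline",
    "stepping_points",
    "root_to_leaf_paths",
]


@dataclass
class CapBoundary:
    """An open boundary loop where the vessel surface meets a cube face."""

    loop: np.ndarray  # (N, 3) ordered boundary vertices, world mm
    center: np.ndarray
    radius: float
    face: int  # 0..5 = (axis, side) as 2*axis + (side > 0)
    role: Literal["source", "target", "unassigned"] = "unassigned"

    @classmethod
    def from_loop(cls, loop: np.ndarray, face: int) -> "CapBoundary":
        loop = np.asarray(loop, dtype=float)
        center = loop.mean(axis=0)
        radius = float(np.linalg.norm(loop - center, axis=1).mean())
        return cls(loop, center, radius, face)


def surface_from_probability(
    prob: ProbabilityVolume | ImageVolume, level: float = 0.5
) -> trimesh.Trimesh:
    """Marching-cubes isosurface of a probability patch, in world mm."""
    data = np.asarray(prob.data, dtype=float)
    if not (data.min() < level <= data.max()):
        raise NoSurface(f"level {level} not crossed (range [{data.min()}, {data.max()}])")
    verts, faces, _, _ = measure.marching_cubes(data, level=level, spacing=tuple(prob.spacing))
    verts = verts + prob.origin[None, :]
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


def _boundary_loops(mesh: trimesh.Trimesh) -> list[np.ndarray]:
    """Ordered vertex loops of edges that border exactly one triangle."""
    if len(mesh.faces) == 0:
        return []
    edges = mesh.edges_sorted
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    boundary = uniq[counts == 1]
    if len(boundary) == 0:
        return []
    adj: dict[int, list[int]] = {}
    for a, b in boundary:
        adj.setdefault(int(a), []).append(int(b))
        adj.setdefault(int(b), []).append(int(a))
    unvisited = {tuple(sorted(e)) for e in boundary}
    loops = []
    while unvisited:
        start_edge = next(iter(unvisited))
        loop = [start_edge[0], start_edge[1]]
        unvisited.discard(start_edge)
        while True:
            cur = loop[-1]
            nxt = None
            for cand in adj.get(cur, ()):
                if tuple(sorted((cur, cand))) in unvisited:
                    nxt = cand
                    break
            if nxt is None:
                break
            unvisited.discard(tuple(sorted((cur, nxt))))
            if nxt == loop[0]:
                break
            loop.append(nxt)
        if len(loop) >= 3:
            loops.append(mesh.vertices[np.array(loop)])
    return loops


def clip_and_caps(
    mesh: trimesh.Trimesh,
    cube: SubvolumeSpec,
    margin: float | None = None,
) -> tuple[trimesh.Trimesh, list[CapBoundary]]:
    """Clip a surface by the six cube faces inset by ``margin`` (mm).

    Returns the clipped mesh and one :class:`CapBoundary` per resulting
    open boundary loop, sorted by (face id, centroid lexicographic).  The
    default margin is one patch voxel, which avoids the degenerate
    triangles marching cubes produces at the array border.
    """
    if margin is None:
        margin = float(np.max(cube.patch_spacing))
    low = cube.low + margin
    high = cube.high - margin
    clipped = mesh
    for axis in range(3):
        for sign, bound in ((+1.0, low[axis]), (-1.0, high[axis])):
            if len(clipped.faces) == 0:
                break
            origin = np.zeros(3)
            origin[axis] = bound
            normal = np.zeros(3)
            normal[axis] = sign
            clipped = clipped.slice_plane(plane_origin=origin, plane_normal=normal)
    caps = []
    for loop in _boundary_loops(clipped):
        centroid = loop.mean(axis=0)
        # nearest inset face
        dists = []
        for axis in range(3):
            dists.append(abs(centroid[axis] - low[axis]))
            dists.append(abs(centroid[axis] - high[axis]))
        face = int(np.argmin(dists))
        cap = CapBoundary.from_loop(loop, face)
        if cap.radius > 0:
            caps.append(cap)
    caps.sort(key=lambda c: (c.face, tuple(np.round(c.center, 9))))
    return clipped, caps


def assign_roles(caps: Sequence[CapBoundary], previous_point) -> list[CapBoundary]:
    """Mark the cap nearest ``previous_point`` as source, the rest as targets.

    Raises :class:`InsufficientOutlets` with fewer than two caps — the
    tracer's trigger for a chance step.
    """
    if len(caps) < 2:
        raise InsufficientOutlets(f"found {len(caps)} cap(s), need >= 2")
    prev = np.asarray(previous_point, dtype=float)
    d = [float(np.linalg.norm(c.center - prev)) for c in caps]
    src = int(np.argmin(d))
    out = []
    for i, c in enumerate(caps):
        role = "source" if i == src else "target"
        out.append(CapBoundary(c.loop, c.center, c.radius, c.face, role))
    return out


def _snap_to_foreground(point: np.ndarray, mask: np.ndarray, volume: ImageVolume) -> np.ndarray:
    fg = np.argwhere(mask)
    world = volume.index_to_world(fg)
    return fg[int(np.argmin(np.linalg.norm(world - point[None, :], axis=1)))]


def _descend(
    T: np.ndarray,
    mask: np.ndarray,
    volume: ImageVolume,
    start_idx: np.ndarray,
    source_world: np.ndarray,
    max_steps: int = 100_000,
) -> np.ndarray:
    """Gradient descent on interpolated T from a target voxel to the source."""
    spacing = volume.spacing
    step = 0.5 * float(spacing.min())
    finite = np.isfinite(T)
    fill = float(T[finite].max()) * 1.5 + 1.0 if np.any(finite) else 1.0
    Tf = np.where(finite, T, fill)
    grads = np.gradient(Tf, *spacing)

    x = volume.index_to_world(start_idx).astype(float)
    path = [x.copy()]
    snap_tol = float(spacing.min())
    last_T = np.inf
    stall = 0
    for _ in range(max_steps):
        if np.linalg.norm(x - source_world) <= snap_tol:
            break
        ci = np.clip(volume.world_to_index(x), 0, np.array(volume.shape) - 1)
        g = np.array(
            [ndimage.map_coordinates(gr, ci[:, None], order=1, mode="nearest")[0] for gr in grads]
        )
        gn = np.linalg.norm(g)
        t_here = float(ndimage.map_coordinates(Tf, ci[:, None], order=1, mode="nearest")[0])
        if gn < 1e-12:
            raise CenterlineFailure("gradient vanished before reaching the source")
        if t_here >= last_T - 1e-12:
            stall += 1
            if stall > 50:
                raise CenterlineFailure("descent stalled (arrival time not decreasing)")
        else:
            stall = 0
            last_T = t_here
        x = x - step * g / gn
        path.append(x.copy())
    else:
        raise CenterlineFailure("descent exceeded the step budget")
    path.append(source_world.copy())
    return np.asarray(path)[::-1]  # source -> target ordering


def _smooth_path(path: np.ndarray, window: int = 5) -> np.ndarray:
    if len(path) <= window:
        return path
    kernel = np.ones(window) / window
    out = path.copy()
    for a in range(3):
        out[:, a] = np.convolve(np.pad(path[:, a], window // 2, mode="edge"), kernel, mode="valid")
    out[0], out[-1] = path[0], path[-1]
    return out


def compute_centerline(
    prob_binarized: LabelVolume,
    source: CapBoundary | np.ndarray,
    targets: Sequence[CapBoundary | np.ndarray],
    speed_clamp_factor: float = 0.1,
) -> CenterlineTree:
    """Wave-propagation centerline of a binarized patch.

    The speed is the Euclidean distance-to-boundary transform clamped below
    at ``speed_clamp_factor * min(spacing)``; arrival times are solved from
    the source cap center (snapped to the nearest foreground voxel) and one
    path per target is traced by gradient descent.  Paths sharing a prefix
    are merged into a tree; the junction is the last shared point.

    Raises :class:`CenterlineFailure` if any target is unreachable
    (disconnected foreground) or descent stalls.
    """
    mask = np.asarray(prob_binarized.data) > 0.5
    if not np.any(mask):
        raise CenterlineFailure("empty foreground")
    spacing = prob_binarized.spacing
    dist = ndimage.distance_transform_edt(mask, sampling=spacing)
    eps = speed_clamp_factor * float(spacing.min())
    speed = np.maximum(dist, eps)

    src_pt = np.asarray(source.center if isinstance(source, CapBoundary) else source, float)
    src_idx = _snap_to_foreground(src_pt, mask, prob_binarized)
    src_world = prob_binarized.index_to_world(src_idx)

    T = eikonal_solve(speed, mask, src_idx, spacing)

    tol = float(spacing.min())
    tree = CenterlineTree(source=src_world.copy())
    tree_points: list[np.ndarray] = []
    tree_owner: list[tuple[int, int]] = []  # (branch id, point index)
    for tgt in targets:
        tgt_pt = np.asarray(tgt.center if isinstance(tgt, CapBoundary) else tgt, float)
        tgt_idx = _snap_to_foreground(tgt_pt, mask, prob_binarized)
        if not np.isfinite(T[tuple(tgt_idx)]):
            raise CenterlineFailure("target unreachable from source (disconnected)")
        path = _descend(T, mask, prob_binarized, tgt_idx, src_world)
        path = _smooth_path(path)
        ci = np.clip(prob_binarized.world_to_index(path).T, 0,
                     (np.array(prob_binarized.shape) - 1)[:, None])
        radii = ndimage.map_coordinates(dist, ci, order=1, mode="nearest")
        radii = np.maximum(radii, eps)

        if not tree.branches:
            parent, start = None, 0
        else:
            kdt = cKDTree(np.asarray(tree_points))
            d, nearest = kdt.query(path)
            run = 0
            while run < len(path) and d[run] <= tol:
                run += 1
            if run == 0:
                parent, start = None, 0
            else:
                parent = tree_owner[int(nearest[run - 1])][0]
                start = max(run - 1, 0)
        seg_pts = path[start:]
        seg_rad = radii[start:]
        if len(seg_pts) < 2:
            continue  # target coincides with an existing branch
        bid = tree.add_branch(Branch(seg_pts, seg_rad, parent))
        for k in range(len(seg_pts)):
            tree_points.append(seg_pts[k])
            tree_owner.append((bid, k))
        tree.targets.append(path[-1].copy())
    if not tree.branches:
        raise CenterlineFailure("no usable source-to-target path")
    return tree


def root_to_leaf_paths(tree: CenterlineTree) -> list[Branch]:
    """Full source-to-target polylines, one per terminal branch.

    A branch is terminal unless a child attaches at its very endpoint
    (children attaching mid-branch leave the branch's own target intact).
    """
    paths = []
    for i, b in enumerate(tree.branches):
        tol = 1e-6 + 0.05 * b.length
        covered = any(
            c.parent == i and np.linalg.norm(c.points[0] - b.points[-1]) <= tol
            for c in tree.branches
        )
        if covered:
            continue
        pts = [b.points]
        rad = [b.radii]
        cur = b
        while cur.parent is not None:
            parent = tree.branches[cur.parent]
            j = int(np.argmin(np.linalg.norm(parent.points - pts[0][0][None, :], axis=1)))
            pts.insert(0, parent.points[: j + 1])
            rad.insert(0, parent.radii[: j + 1])
            cur = parent
        allp = np.vstack(pts)
        allr = np.concatenate(rad)
        # drop consecutive duplicates
        keep = np.concatenate([[True], np.linalg.norm(np.diff(allp, axis=0), axis=1) > 1e-9])
        paths.append(Branch(allp[keep], allr[keep], None))
    return paths


def stepping_points(
    tree: CenterlineTree, fraction: float = 0.8
) -> list[tuple[np.ndarray, np.ndarray, float]]:
    """(point, unit tangent, radius) at ``fraction`` of each path's arclength.

    One stepping point per source-to-target path; tangents point along the
    direction of travel (source toward target).
    """
    out = []
    for path in root_to_leaf_paths(tree):
        point, tangent, radius = path.point_at(fraction * path.length)
        out.append((point, tangent, float(radius)))
    return out
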