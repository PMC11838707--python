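"""Synthetic tubular-tree phantoms.

Generates (image, label, centerline-with-radius) triples that emulate a
contrast-filled vessel tree: a bright tube on a darker background with
additive Gaussian noise, optional noise-corrupted boxes (to exercise the
tracer's chance mechanism), and exact ground-truth centerlines.

The lumen is modelled as the union of balls swept along each branch
polyline with linearly tapering radii, i.e. a capsule chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .centerline import Branch, CenterlineTree
from .errors import InvalidGeometry, TreeOutOfGrid
from .volume import ImageVolume, LabelVolume

__all__ = ["PhantomBranch", "TreeSpec", "PhantomConfig", "generate_tree", "voxelize"]


@dataclass
class PhantomBranch:
    """One tube of the synthetic tree."""

    polyline: np.ndarray  # (N, 3) world mm
    radius_profile: np.ndarray  # (N,) mm
    parent: int | None = None
    attach_arclength: float = 0.0

    def __post_init__(self) -> None:
        self.polyline = np.asarray(self.polyline, dtype=float).reshape(-1, 3)
        self.radius_profile = np.asarray(self.radius_profile, dtype=float).reshape(-1)
        if len(self.polyline) < 2:
            raise InvalidGeometry("branch polyline needs >= 2 points")
        if len(self.polyline) != len(self.radius_profile):
            raise InvalidGeometry("polyline/radius_profile length mismatch")
        if np.any(self.radius_profile <= 0):
            raise InvalidGeometry("radii must be positive")


@dataclass
class TreeSpec:
    """A rooted collection of branches; branch 0 is the root."""

    branches: list[PhantomBranch] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, b in enumerate(self.branches):
            if b.parent is None:
                continue
            if not (0 <= b.parent < i):
                raise InvalidGeometry(
                    f"branch {i}: parent {b.parent} must precede it (rooted tree)"
                )
            parent = self.branches[b.parent]
            d = np.linalg.norm(parent.polyline - b.polyline[0], axis=1)
            j = int(np.argmin(d))
            if d[j] > 1e-6:
                raise InvalidGeometry(
                    f"branch {i}: first point is {d[j]:.3g} mm off its parent"
                )
            if b.radius_profile[0] > parent.radius_profile[j] + 1e-9:
                raise InvalidGeometry(
                    f"branch {i}: child radius {b.radius_profile[0]:.3g} exceeds "
                    f"parent radius {parent.radius_profile[j]:.3g} at the attachment"
                )

    def to_centerline_tree(self) -> CenterlineTree:
        tree = CenterlineTree(
            branches=[Branch(b.polyline.copy(), b.radius_profile.copy(), b.parent)
                      for b in self.branches],
            source=self.branches[0].polyline[0].copy() if self.branches else None,
        )
        children = {b.parent for b in self.branches if b.parent is not None}
        for i, b in enumerate(self.branches):
            if i not in children:
                tree.targets.append(b.polyline[-1].copy())
        return tree


@dataclass
class PhantomConfig:
    """Rasterization settings for :func:`voxelize`.

    Intensities default to a CT-angiography-like contrast: lumen at 100,
    background at 0, noise sd 10 (a contrast-to-noise ratio of 10).
    """

    grid_shape: tuple[int, int, int] = (128, 128, 128)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    vessel_intensity: float = 100.0
    background_intensity: float = 0.0
    noise_sd: float = 10.0
    corruption_boxes: list[tuple[tuple[float, float, float], tuple[float, float, float]]] = field(
        default_factory=list
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vessel_intensity == self.background_intensity:
            raise InvalidGeometry("vessel and background intensity must differ")
        if self.noise_sd < 0:
            raise InvalidGeometry("noise_sd must be >= 0")


def _segment(start, direction, length, r0, r1, step):
    """Straight polyline from start along unit direction, linear radius taper."""
    n = max(2, int(np.ceil(length / step)) + 1)
    t = np.linspace(0.0, length, n)
    pts = np.asarray(start)[None, :] + t[:, None] * np.asarray(direction)[None, :]
    radii = r0 + (r1 - r0) * t / length
    return pts, radii


def _perpendicular(direction, rng):
    """A unit vector perpendicular to ``direction`` with random roll."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(d, ref)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    phi = rng.uniform(0, 2 * np.pi)
    return np.cos(phi) * u + np.sin(phi) * v


def generate_tree(
    kind: str,
    *,
    start=(10.0, 64.0, 64.0),
    direction=(1.0, 0.0, 0.0),
    length: float = 100.0,
    radius: float = 4.0,
    radius_end: float | None = None,
    child_ratio: float = 0.7,
    length_ratio: float = 0.7,
    branch_angle_deg: tuple[float, float] = (30.0, 45.0),
    generations: int = 2,
    rng=None,
) -> TreeSpec:
    """Build a synthetic vessel tree.

    ``kind`` is one of ``tube`` (a single straight tapering tube),
    ``y_bifurcation`` (a parent splitting into two children at its end) or
    ``n_generation_tree`` (a recursive binary tree with ``generations``
    levels of children).  Child radii are ``child_ratio`` times the parent's
    end radius; branching angles are drawn uniformly from
    ``branch_angle_deg`` and children are placed symmetrically about the
    parent direction.
    """
    if radius <= 0 or length <= 0:
        raise InvalidGeometry("radius and length must be positive")
    if generations < 0:
        raise InvalidGeometry("generations must be >= 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    r_end = radius if radius_end is None else radius_end
    if r_end <= 0:
        raise InvalidGeometry("radius_end must be positive")
    d0 = np.asarray(direction, dtype=float)
    d0 = d0 / np.linalg.norm(d0)
    step = max(0.25, radius / 4.0)

    branches: list[PhantomBranch] = []
    pts, radii = _segment(np.asarray(start, float), d0, length, radius, r_end, step)
    branches.append(PhantomBranch(pts, radii, None, 0.0))

    if kind == "tube":
        return TreeSpec(branches)

    if kind == "y_bifurcation":
        levels = 1
    elif kind == "n_generation_tree":
        levels = generations
    else:
        raise ValueError(f"unknown tree kind {kind!r}")

    # breadth-first growth: (branch index, depth)
    frontier = [(0, 0)]
    while frontier:
        parent_idx, depth = frontier.pop(0)
        if depth >= levels:
            continue
        parent = branches[parent_idx]
        tip = parent.polyline[-1]
        pdir = parent.polyline[-1] - parent.polyline[-2]
        pdir = pdir / np.linalg.norm(pdir)
        pr = parent.radius_profile[-1]
        cr = child_ratio * pr
        clen = length * length_ratio ** (depth + 1)
        angle = np.deg2rad(rng.uniform(*branch_angle_deg))
        perp = _perpendicular(pdir, rng)
        for sign in (+1.0, -1.0):
            cdir = np.cos(angle) * pdir + sign * np.sin(angle) * perp
            cdir /= np.linalg.norm(cdir)
            cstep = max(0.25, cr / 4.0)
            pts, radii = _segment(tip, cdir, clen, cr, cr, cstep)
            ci = len(branches)
            branches.append(
                PhantomBranch(pts, radii, parent_idx, float(np.linalg.norm(tip - parent.polyline[0])))
            )
            frontier.append((ci, depth + 1))
    return TreeSpec(branches)


def voxelize(
    tree: TreeSpec,
    config: PhantomConfig,
    allow_exit: bool = False,
) -> tuple[ImageVolume, LabelVolume, CenterlineTree]:
    """Rasterize a tree onto the phantom grid.

    The label is 1 exactly where a voxel center lies within the local
    radius of the swept centerline.  The image is ``vessel_intensity``
    inside and ``background_intensity`` outside, plus seeded Gaussian
    noise; corruption boxes are overwritten with structureless noise.

    With ``allow_exit=False`` a tube leaving the grid raises
    :class:`TreeOutOfGrid`; pass ``allow_exit=True`` to build
    boundary-stop test cases.
    """
    shape = tuple(int(n) for n in config.grid_shape)
    spacing = np.asarray(config.spacing, dtype=float)
    origin = np.asarray(config.origin, dtype=float)
    world_max = origin + (np.array(shape) - 1) * spacing

    label = np.zeros(shape, dtype=np.uint8)
    sample_step = 0.5 * float(spacing.min())
    for bi, branch in enumerate(tree.branches):
        dense = Branch(branch.polyline, branch.radius_profile).resample(sample_step)
        if not allow_exit:
            lo = dense.points - dense.radii[:, None]
            hi = dense.points + dense.radii[:, None]
            if np.any(lo < origin - 1e-9) or np.any(hi > world_max + 1e-9):
                raise TreeOutOfGrid(f"branch {bi} exits the phantom grid")
        # stamp a ball at every dense sample
        for p, r in zip(dense.points, dense.radii):
            i_lo = np.maximum(np.ceil((p - r - origin) / spacing), 0).astype(int)
            i_hi = np.minimum(np.floor((p + r - origin) / spacing), np.array(shape) - 1).astype(int)
            if np.any(i_hi < i_lo):
                continue
            ax = [origin[a] + np.arange(i_lo[a], i_hi[a] + 1) * spacing[a] for a in range(3)]
            dx2 = (ax[0] - p[0]) ** 2
            dy2 = (ax[1] - p[1]) ** 2
            dz2 = (ax[2] - p[2]) ** 2
            ball = (
                dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]
            ) <= r * r + 1e-12
            label[
                i_lo[0] : i_hi[0] + 1, i_lo[1] : i_hi[1] + 1, i_lo[2] : i_hi[2] + 1
            ] |= ball.astype(np.uint8)

    rng = np.random.default_rng(config.seed)
    image = np.where(
        label > 0, float(config.vessel_intensity), float(config.background_intensity)
    )
    if config.noise_sd > 0:
        image = image + rng.normal(0.0, config.noise_sd, size=shape)

    contrast = abs(config.vessel_intensity - config.background_intensity)
    mid = 0.5 * (config.vessel_intensity + config.background_intensity)
    for lo_w, hi_w in config.corruption_boxes:
        lo_w = np.asarray(lo_w, dtype=float)
        hi_w = np.asarray(hi_w, dtype=float)
        i_lo = np.maximum(np.ceil((lo_w - origin) / spacing), 0).astype(int)
        i_hi = np.minimum(np.floor((hi_w - origin) / spacing), np.array(shape) - 1).astype(int)
        if np.any(i_hi < i_lo):
            continue
        box_shape = tuple(i_hi - i_lo + 1)
        image[
            i_lo[0] : i_hi[0] + 1, i_lo[1] : i_hi[1] + 1, i_lo[2] : i_hi[2] + 1
        ] = rng.normal(mid, 0.5 * contrast, size=box_shape)

    image_vol = ImageVolume(image, spacing, origin)
    label_vol = LabelVolume(label, spacing, origin)
    return image_vol, label_vol, tree.to_centerline_tree()
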