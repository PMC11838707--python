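"""Training-patch sampling along centerlines, and the segmentation loss.

Patches are cubes whose side length is a random multiple of the local
vessel radius, ``L = alpha * R`` with ``alpha ~ N(mu_r, sigma_r^2)``, and
whose center is shifted off the centerline within the perpendicular plane,
``c = C + beta * R * w`` with ``beta ~ N(mu_s, sigma_s^2)`` and ``w`` a
random unit vector perpendicular to the local tangent.  The defaults
(``mu_r = 5``, ``sigma_r^2 = 1``; ``mu_s = 0``, ``sigma_s^2 = 0.8``) make
the mean patch five radii wide and centered on the vessel, with enough
jitter to mimic the misalignment the tracer produces at inference.

The training loss pairs a soft Dice term with binary cross-entropy; it is
exposed here so a learned backend trained elsewhere can be verified against
the same definition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .centerline import CenterlineTree
from .errors import DegenerateTangent, EmptyDataset, OutOfBounds, ShapeMismatch
from .volume import (
    ImageVolume,
    LabelVolume,
    ProbabilityVolume,
    SubvolumeSpec,
    extract_subvolume,
)

__all__ = [
    "SamplerConfig",
    "FrameSample",
    "PatchPair",
    "perpendicular_frame",
    "draw_patch",
    "build_patch_dataset",
    "training_loss",
]

log = logging.getLogger(__name__)

#: below this multiple of R a cube cannot contain the lumen; alpha draws are
#: truncated (redrawn) at this floor
ALPHA_FLOOR = 2.0


@dataclass(frozen=True)
class SamplerConfig:
    """Patch-size and patch-shift distribution parameters.

    ``sigma_r`` and ``sigma_s`` are standard deviations; the default shift
    variance of 0.8 corresponds to ``sigma_s = sqrt(0.8)``.
    """

    mu_r: float = 5.0
    sigma_r: float = 1.0
    mu_s: float = 0.0
    sigma_s: float = float(np.sqrt(0.8))
    alpha_floor: float = ALPHA_FLOOR
    grid_shape: tuple[int, int, int] = (64, 64, 64)

    def __post_init__(self) -> None:
        if self.mu_r <= 0:
            raise ValueError("mu_r must be positive")
        if self.sigma_r < 0 or self.sigma_s < 0:
            raise ValueError("sigmas must be >= 0")


@dataclass(frozen=True)
class FrameSample:
    """The in-plane direction draw: w = (a*u + b*v) / ||a*u + b*v||."""

    u: np.ndarray
    v: np.ndarray
    a: float
    b: float
    w: np.ndarray


@dataclass
class PatchPair:
    """An (image, label) patch pair with its provenance."""

    X: ImageVolume
    Y_t: LabelVolume
    spec: SubvolumeSpec
    branch: int
    arclength: float


def perpendicular_frame(tangent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal ``(u, v)`` spanning the plane perpendicular to ``tangent``."""
    t = np.asarray(tangent, dtype=float)
    norm = np.linalg.norm(t)
    if norm < 1e-12:
        raise DegenerateTangent("tangent vector is (near) zero")
    t = t / norm
    ref = np.array([1.0, 0.0, 0.0]) if abs(t[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(t, ref)
    u /= np.linalg.norm(u)
    v = np.cross(t, u)
    return u, v


def sample_frame(tangent: np.ndarray, rng: np.random.Generator) -> FrameSample:
    """Draw a random unit vector in the plane perpendicular to the tangent."""
    u, v = perpendicular_frame(tangent)
    while True:
        a, b = rng.uniform(-1.0, 1.0, size=2)
        vec = a * u + b * v
        n = np.linalg.norm(vec)
        if n > 1e-9:
            return FrameSample(u, v, float(a), float(b), vec / n)


def draw_patch(
    C: np.ndarray,
    R: float,
    tangent: np.ndarray,
    config: SamplerConfig,
    rng: np.random.Generator,
) -> SubvolumeSpec:
    """Draw one patch cube around centerline point ``C`` with local radius ``R``.

    The side length is ``alpha * R`` (``alpha`` normal, truncated below at
    ``config.alpha_floor`` by redrawing) and the center is shifted by
    ``beta * R`` along a random in-plane unit vector.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    frame = sample_frame(tangent, rng)
    while True:
        alpha = rng.normal(config.mu_r, config.sigma_r)
        if alpha >= config.alpha_floor:
            break
    beta = rng.normal(config.mu_s, config.sigma_s)
    center = np.asarray(C, dtype=float) + beta * R * frame.w
    return SubvolumeSpec(tuple(center), float(alpha * R), config.grid_shape)


def build_patch_dataset(
    image: ImageVolume,
    label: LabelVolume,
    centerline: CenterlineTree,
    samples_per_point: int = 1,
    config: SamplerConfig | None = None,
    rng=None,
    point_interval_radii: float = 0.5,
    max_retries: int = 5,
) -> list[PatchPair]:
    """Sample (image, label) patch pairs along every centerline branch.

    Sample points are spaced at ``point_interval_radii`` times the local
    radius along each branch; ``samples_per_point`` stochastic cubes are
    drawn at each.  Draws whose cube leaves the image are redrawn up to
    ``max_retries`` times, then skipped with a log record.
    """
    if not image.same_grid(label):
        raise ShapeMismatch("image and label must share a grid")
    config = config or SamplerConfig()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    pairs: list[PatchPair] = []
    for bi, branch in enumerate(centerline.branches):
        interval = max(point_interval_radii * float(branch.radii.mean()), 1e-3)
        svals = np.arange(0.0, branch.length + 1e-9, interval)
        for s in svals:
            C, tangent, R = branch.point_at(float(s))
            for _ in range(samples_per_point):
                for attempt in range(max_retries + 1):
                    spec = draw_patch(C, R, tangent, config, rng)
                    try:
                        X = extract_subvolume(image, spec, kind="image")
                        Y = extract_subvolume(label, spec, kind="label")
                    except OutOfBounds:
                        continue
                    pairs.append(PatchPair(X, Y, spec, bi, float(s)))
                    break
                else:
                    log.info(
                        "skipped a draw at branch %d, s=%.2f mm: cube outside image",
                        bi, s,
                    )
    if not pairs:
        raise EmptyDataset("every patch draw fell outside the image")
    return pairs


def training_loss(
    Y_p: ProbabilityVolume | np.ndarray,
    Y_t: LabelVolume | np.ndarray,
    eps: float = 1e-7,
) -> tuple[float, float, float]:
    """Soft-Dice + binary-cross-entropy loss.

    Returns ``(loss, dice_term, bce_term)`` where ``dice_term`` is the soft
    Dice score (voxelwise product as intersection), ``bce_term`` the mean
    binary cross-entropy with predictions clamped to ``[eps, 1-eps]``, and
    ``loss = (1 - dice_term) + bce_term`` — the quantity a trainer minimizes.
    """
    p = np.asarray(Y_p.data if isinstance(Y_p, ImageVolume) else Y_p, dtype=float)
    t = np.asarray(Y_t.data if isinstance(Y_t, ImageVolume) else Y_t, dtype=float)
    if p.shape != t.shape:
        raise ShapeMismatch(f"prediction {p.shape} vs target {t.shape}")
    inter = float((p * t).sum())
    denom = float(p.sum() + t.sum())
    dice = 1.0 if denom == 0 else 2.0 * inter / denom
    pc = np.clip(p, eps, 1.0 - eps)
    bce = float(-(t * np.log(pc) + (1.0 - t) * np.log(1.0 - pc)).mean())
    return (1.0 - dice) + bce, dice, bce
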