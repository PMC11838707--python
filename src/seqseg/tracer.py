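"""The sequential tracing loop.

Starting from a single seed (point, direction, radius estimate), the
tracer repeatedly: sizes a cubic subvolume from the running radius
estimate, segments it with the plugged-in backend, extracts the local
surface and centerline, steps 80% of the way along the chosen branch, and
queues every other outlet as a bifurcation to revisit later.  Local
failures (no surface, fewer than two outlets, centerline failure, backend
errors) consume bounded "chances" — blind steps of one radius in the
current direction — before the branch is abandoned.  Every accepted local
prediction is pushed into the global assembly accumulator.

Stop criteria: the image boundary (a requested cube leaves the volume),
low subvolume resolution, exhausted chances, a minimum radius, a maximum
total step count and a maximum branch count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .assembler import AssemblyAccumulator
from .centerline import Branch, CenterlineTree
from .errors import (
    BackendFailure,
    CenterlineFailure,
    ChancesExhausted,
    InsufficientOutlets,
    NoSurface,
    OutOfBounds,
    SeedOutsideImage,
    SeedSegmentationFailure,
)
from .geometry import (
    assign_roles,
    clip_and_caps,
    compute_centerline,
    root_to_leaf_paths,
    stepping_points,
    surface_from_probability,
)
from .segmenters import Segmenter, segment
from .volume import ImageVolume, LabelVolume, ProbabilityVolume, SubvolumeSpec, extract_subvolume

__all__ = [
    "TracerConfig",
    "TraceState",
    "QueueEntry",
    "TraceResult",
    "next_sidelength",
    "adaptive_subvolume",
    "chance_step",
    "is_retraced",
    "run_trace",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TracerConfig:
    """Knobs of the tracing loop.

    ``gamma_star`` is the predicted-vessel fill fraction above which the
    subvolume is enlarged (a 5R cube around a straight vessel of radius R
    fills ~ pi/25 ~ 0.13 of it, so 0.2 flags an undersized cube).
    ``sidelength_factor`` relates cube side to radius (L = factor * mean
    radius).  ``r_min`` is in mm.  ``min_voxels_per_axis`` is the
    low-resolution stop: a cube spanning fewer native voxels per axis than
    this ends the branch.  ``dedup_radius_factor`` suppresses duplicate
    bifurcation detections: a candidate outlet within this multiple of the
    larger radius of an existing queue entry (or a previously traced
    stepping point) is dropped.
    """

    gamma_star: float = 0.2
    chance_max: int = 3
    n_max: int = 500
    r_min: float = 0.5
    nb_max: int = 15
    sidelength_factor: float = 5.0
    enlarge_factor: float = 1.1
    enlarge_cap: float = 1.3
    retrace_check_period: int = 5
    retrace_overlap: float = 0.8
    buffer_steps: int = 3
    step_fraction: float = 0.8
    surface_level: float = 0.5
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    min_voxels_per_axis: int = 8
    dedup_radius_factor: float = 2.0

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma_star < 1.0):
            raise ValueError("gamma_star must be in (0, 1)")
        if self.enlarge_factor <= 1.0:
            raise ValueError("enlarge_factor must exceed 1")
        if self.enlarge_cap < self.enlarge_factor:
            raise ValueError("enlarge_cap must be >= enlarge_factor")


@dataclass
class TraceState:
    """The tracer's moving frame along the current branch."""

    point: np.ndarray
    tangent: np.ndarray
    radius: float
    radius_prev: float
    previous_point: np.ndarray
    chances_used: int = 0
    step_index: int = 0
    branch_id: int = 0

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        t = np.asarray(self.tangent, dtype=float)
        n = np.linalg.norm(t)
        if n == 0:
            raise ValueError("tangent must be nonzero")
        self.tangent = t / n
        self.previous_point = np.asarray(self.previous_point, dtype=float)
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass
class QueueEntry:
    """A stored bifurcation: an outlet not chosen for continuation."""

    point: np.ndarray
    tangent: np.ndarray
    radius: float
    parent_branch: int | None = None

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        self.tangent = np.asarray(self.tangent, dtype=float)
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass
class TraceResult:
    """Everything a finished run produces."""

    accumulator: AssemblyAccumulator
    centerline: CenterlineTree
    logs: list[dict] = field(default_factory=list)
    termination_reasons: list[tuple[int, str]] = field(default_factory=list)
    queue_entries_created: int = 0
    branches_traced: int = 0
    total_steps: int = 0
    segmentation_calls: int = 0


def next_sidelength(r_i: float, r_prev: float | None = None, factor: float = 5.0) -> float:
    """Cube side from the running radius estimate: L = factor * (r_i + r_{i-1}) / 2."""
    if r_prev is None:
        r_prev = r_i
    if r_i <= 0 or r_prev <= 0:
        raise ValueError("radii must be positive")
    return factor * (r_i + r_prev) / 2.0


def _gamma(prob: ProbabilityVolume) -> float:
    return float(np.mean(np.asarray(prob.data) >= 0.5))


def adaptive_subvolume(
    image: ImageVolume,
    center: np.ndarray,
    r_i: float,
    r_prev: float,
    backend: Segmenter,
    config: TracerConfig,
) -> tuple[SubvolumeSpec, ProbabilityVolume, float, int]:
    """Segment a subvolume, enlarging it while the vessel fills too much of it.

    Starts at ``L0 = sidelength_factor * (r_i + r_prev)/2``.  While the
    predicted fill fraction gamma is at least ``gamma_star``, the side is
    multiplied by ``enlarge_factor`` (compounding) and re-segmented; the
    loop breaks once ``L/L0`` exceeds ``enlarge_cap``.  If an enlarged cube
    would leave the image, the last in-bounds result is kept.

    Returns ``(spec, prediction, gamma, segmentation_calls)``.
    """
    L0 = next_sidelength(r_i, r_prev, config.sidelength_factor)
    spec = SubvolumeSpec(tuple(center), L0, config.grid_shape)
    patch = extract_subvolume(image, spec)  # may raise OutOfBounds
    prob = segment(backend, patch)
    gamma = _gamma(prob)
    calls = 1
    L = L0
    while gamma >= config.gamma_star:
        L = L * config.enlarge_factor
        try:
            bigger = SubvolumeSpec(tuple(center), L, config.grid_shape)
            patch = extract_subvolume(image, bigger)
            prob = segment(backend, patch)
        except OutOfBounds:
            break  # keep the last in-bounds result
        spec = bigger
        gamma = _gamma(prob)
        calls += 1
        if L / L0 > config.enlarge_cap:
            break
    return spec, prob, gamma, calls


def chance_step(state: TraceState, config: TracerConfig | None = None) -> TraceState:
    """Advance blindly one radius along the current tangent.

    Raises :class:`ChancesExhausted` once the consecutive-failure budget
    (``chance_max``) is spent; a successful step resets the counter.
    """
    chance_max = (config or TracerConfig()).chance_max
    if state.chances_used >= chance_max:
        raise ChancesExhausted(f"{state.chances_used} chances already used")
    return replace(
        state,
        point=state.point + state.radius * state.tangent,
        chances_used=state.chances_used + 1,
    )


def is_retraced(
    accumulator: AssemblyAccumulator,
    candidate_spec: SubvolumeSpec,
    prediction: ProbabilityVolume,
    recent_contributions: list,
    config: TracerConfig,
) -> bool:
    """Has this region already been segmented by a *previous* branch?

    Measures the fraction of the candidate prediction's foreground voxels
    whose global read-out — with the current branch's last
    ``buffer_steps`` contributions subtracted — is already above the
    assembly threshold.  True when that fraction exceeds
    ``retrace_overlap``.
    """
    sl, _, s = accumulator.contribution(prediction, candidate_spec)
    fg = s >= 0.5
    if not fg.any():
        return False
    read = accumulator.read_out(exclude=list(recent_contributions))
    already = np.asarray(read.data)[sl][fg] >= 0.5
    return float(already.mean()) > config.retrace_overlap


def _near_known(point: np.ndarray, radius: float, known: list, factor: float) -> bool:
    for kp, kr in known:
        if np.linalg.norm(point - kp) <= factor * max(radius, kr):
            return True
    return False


def run_trace(
    image: ImageVolume,
    seed: tuple,
    backend: Segmenter,
    config: TracerConfig | None = None,
) -> TraceResult:
    """Trace the full vessel tree reachable from one seed.

    ``seed`` is ``(point, direction, radius)`` in world mm.  The branch
    queue is re-sorted by radius at every pop so the largest vessels are
    traced first; the fictitious previous stepping point of a fresh branch
    is ``point - radius * direction``, which makes the upstream cap the
    source.
    """
    config = config or TracerConfig()
    seed_point = np.asarray(seed[0], dtype=float)
    seed_dir = np.asarray(seed[1], dtype=float)
    seed_radius = float(seed[2])
    if not image.contains_point(seed_point):
        raise SeedOutsideImage(f"seed {seed_point} outside image extent")
    if seed_radius <= 0:
        raise ValueError("seed radius must be positive")
    n = np.linalg.norm(seed_dir)
    if n == 0:
        raise ValueError("seed direction must be nonzero")
    seed_dir = seed_dir / n

    acc = AssemblyAccumulator(image)
    result = TraceResult(accumulator=acc, centerline=CenterlineTree(source=seed_point.copy()))
    queue: list[QueueEntry] = [QueueEntry(seed_point, seed_dir, seed_radius, None)]
    # (point, radius) of everything already explored, for duplicate-outlet
    # suppression; keyed by the branch that produced it
    known_points: list[tuple[np.ndarray, float, int]] = []
    first_attempt = True
    run_over = False

    while queue and not run_over:
        if result.branches_traced >= config.nb_max:
            result.termination_reasons.append((-1, "max_branches"))
            break
        queue.sort(key=lambda e: -e.radius)
        entry = queue.pop(0)
        branch_id = result.branches_traced
        result.branches_traced += 1
        # the entry's own neighbourhood is about to be traced by this branch;
        # stop treating it as already-explored territory
        known_points = [
            (kp, kr, kb)
            for (kp, kr, kb) in known_points
            if not (np.allclose(kp, entry.point) and np.isclose(kr, entry.radius))
        ]

        state = TraceState(
            point=entry.point,
            tangent=entry.tangent,
            radius=entry.radius,
            radius_prev=entry.radius,
            previous_point=entry.point - entry.radius * np.asarray(entry.tangent) / np.linalg.norm(entry.tangent),
            branch_id=branch_id,
        )
        recent: list = []  # last buffer_steps contributions of this branch
        branch_polyline: list[np.ndarray] = [state.point.copy()]
        branch_radii: list[float] = [state.radius]
        accepted = 0
        reason = None

        while reason is None:
            if result.total_steps >= config.n_max:
                reason = "max_steps"
                run_over = True
                break
            if state.radius < config.r_min:
                reason = "min_radius"
                break
            L0 = next_sidelength(state.radius, state.radius_prev, config.sidelength_factor)
            if np.any(L0 / image.spacing < config.min_voxels_per_axis):
                reason = "low_resolution"
                break

            failure = None
            try:
                spec, prob, gamma, calls = adaptive_subvolume(
                    image, state.point, state.radius, state.radius_prev, backend, config
                )
                result.segmentation_calls += calls
            except OutOfBounds:
                reason = "image_boundary"
                break
            except BackendFailure as exc:
                failure = f"backend: {exc}"
                spec = prob = None

            points = []
            if failure is None:
                try:
                    mesh = surface_from_probability(prob, config.surface_level)
                    _, caps = clip_and_caps(mesh, spec)
                    caps = assign_roles(caps, state.previous_point)
                    binar = LabelVolume(
                        (np.asarray(prob.data) >= 0.5).astype(np.uint8),
                        prob.spacing,
                        prob.origin,
                    )
                    source = next(c for c in caps if c.role == "source")
                    targets = [c for c in caps if c.role == "target"]
                    local = compute_centerline(binar, source, targets)
                    points = stepping_points(local, config.step_fraction)
                except NoSurface as exc:
                    if first_attempt:
                        raise SeedSegmentationFailure(
                            "the first subvolume produced no vessel surface"
                        ) from exc
                    failure = f"no surface: {exc}"
                except (InsufficientOutlets, CenterlineFailure) as exc:
                    failure = f"{type(exc).__name__}: {exc}"
            first_attempt = False

            if failure is None and points:
                # periodic retracing check: has a *previous* branch already
                # segmented this region?
                if accepted > 0 and accepted % config.retrace_check_period == 0:
                    if is_retraced(acc, spec, prob, recent, config):
                        reason = "retraced"
                        break
                # drop outlets that lead back into already-explored territory
                fresh = [
                    (p, t, r)
                    for (p, t, r) in points
                    if not _near_known(
                        p,
                        r,
                        [(kp, kr) for kp, kr, kb in known_points if kb != branch_id],
                        config.dedup_radius_factor,
                    )
                ]
                if not fresh:
                    reason = "already_traced"
                    break
                fresh.sort(key=lambda x: -x[2])
                chosen = fresh[0]
                for p, t, r in fresh[1:]:
                    queue.append(QueueEntry(p, t, r, branch_id))
                    known_points.append((np.asarray(p), float(r), branch_id))
                    result.queue_entries_created += 1

                contrib = acc.contribution(prob, spec)
                sl, w, s = contrib
                acc.weighted_sum[sl] += w * s
                acc.weight_sum[sl] += w
                acc.contribution_count[sl] += 1
                recent.append(contrib)
                if len(recent) > config.buffer_steps:
                    recent.pop(0)

                result.logs.append(
                    {
                        "branch": branch_id,
                        "step": result.total_steps,
                        "action": "step",
                        "L": spec.sidelength,
                        "gamma": gamma,
                        "caps": len(caps),
                        "outcome": "accepted",
                    }
                )
                known_points.append((state.point.copy(), state.radius, branch_id))
                new_point, new_tangent, new_radius = chosen
                state = TraceState(
                    point=np.asarray(new_point),
                    tangent=np.asarray(new_tangent),
                    radius=float(new_radius),
                    radius_prev=state.radius,
                    previous_point=state.point.copy(),
                    chances_used=0,
                    step_index=state.step_index + 1,
                    branch_id=branch_id,
                )
                branch_polyline.append(state.point.copy())
                branch_radii.append(state.radius)
                accepted += 1
                result.total_steps += 1
            else:
                result.logs.append(
                    {
                        "branch": branch_id,
                        "step": result.total_steps,
                        "action": "chance",
                        "L": None if spec is None else spec.sidelength,
                        "gamma": None,
                        "caps": None,
                        "outcome": failure,
                    }
                )
                try:
                    state = chance_step(state, config)
                except ChancesExhausted:
                    reason = "chances_exhausted"
                    break

        result.termination_reasons.append((branch_id, reason or "unknown"))
        log.info("branch %d ended after %d step(s): %s", branch_id, accepted, reason)
        if accepted >= 1:
            result.centerline.add_branch(
                Branch(
                    np.asarray(branch_polyline),
                    np.asarray(branch_radii),
                    entry.parent_branch,
                )
            )
    return result
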