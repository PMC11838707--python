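"""Centerline trees: ordered 3D polylines with per-point radii.

A :class:`CenterlineTree` is the common currency between the phantom
generator (ground truth), the local geometry stage (per-patch centerlines)
and the evaluation metrics.  Branches are stored in a flat list; each
branch optionally points at a parent branch, and a branch's first point is
either the tree source or a junction on its parent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Branch", "CenterlineTree"]


@dataclass
class Branch:
    """An ordered polyline with a radius at every point."""

    points: np.ndarray  # (N, 3) world mm
    radii: np.ndarray  # (N,) mm
    parent: int | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float).reshape(-1)
        if len(self.points) < 2:
            raise ValueError("a branch needs at least 2 points")
        if len(self.points) != len(self.radii):
            raise ValueError("points and radii lengths differ")
        if np.any(self.radii <= 0):
            raise ValueError("radii must be positive")

    @property
    def arclengths(self) -> np.ndarray:
        """Cumulative arclength at each point, starting at 0."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arclengths[-1])

    def point_at(self, s: float) -> tuple[np.ndarray, np.ndarray, float]:
        """Point, unit tangent and radius at arclength ``s`` (clamped)."""
        cum = self.arclengths
        s = float(np.clip(s, 0.0, cum[-1]))
        i = int(np.searchsorted(cum, s, side="right") - 1)
        i = min(i, len(cum) - 2)
        seg = cum[i + 1] - cum[i]
        t = 0.0 if seg == 0 else (s - cum[i]) / seg
        point = (1 - t) * self.points[i] + t * self.points[i + 1]
        radius = (1 - t) * self.radii[i] + t * self.radii[i + 1]
        # central-difference tangent on the polyline
        lo, hi = max(i - 1, 0), min(i + 2, len(self.points) - 1)
        tangent = self.points[hi] - self.points[lo]
        norm = np.linalg.norm(tangent)
        if norm == 0:
            tangent = self.points[i + 1] - self.points[i]
            norm = np.linalg.norm(tangent)
        return point, tangent / norm, float(radius)

    def resample(self, interval: float) -> "Branch":
        """Resample at (approximately) fixed arclength ``interval``."""
        n = max(2, int(np.ceil(self.length / interval)) + 1)
        svals = np.linspace(0.0, self.length, n)
        pts = np.empty((n, 3))
        rad = np.empty(n)
        cum = self.arclengths
        idx = np.clip(np.searchsorted(cum, svals, side="right") - 1, 0, len(cum) - 2)
        seg = cum[idx + 1] - cum[idx]
        frac = np.where(seg > 0, (svals - cum[idx]) / np.where(seg > 0, seg, 1.0), 0.0)
        pts = (1 - frac)[:, None] * self.points[idx] + frac[:, None] * self.points[idx + 1]
        rad = (1 - frac) * self.radii[idx] + frac * self.radii[idx + 1]
        return Branch(pts, rad, self.parent)


@dataclass
class CenterlineTree:
    """A rooted collection of branches with a source and target points."""

    branches: list[Branch] = field(default_factory=list)
    source: np.ndarray | None = None
    targets: list[np.ndarray] = field(default_factory=list)

    def add_branch(self, branch: Branch) -> int:
        self.branches.append(branch)
        return len(self.branches) - 1

    @property
    def total_length(self) -> float:
        return float(sum(b.length for b in self.branches))

    def all_samples(self, interval: float) -> tuple[np.ndarray, np.ndarray]:
        """All branch points resampled at ``interval``: (points, radii)."""
        pts, rad = [], []
        for b in self.branches:
            rb = b.resample(interval)
            pts.append(rb.points)
            rad.append(rb.radii)
        if not pts:
            return np.empty((0, 3)), np.empty(0)
        return np.vstack(pts), np.concatenate(rad)

    # --- plain-text serialization (JSON dialect) ----------------------------

    def to_dict(self) -> dict:
        return {
            "source": None if self.source is None else list(map(float, self.source)),
            "targets": [list(map(float, t)) for t in self.targets],
            "branches": [
                {
                    "points": b.points.tolist(),
                    "radii": b.radii.tolist(),
                    "parent": b.parent,
                }
                for b in self.branches
            ],
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, d: dict) -> "CenterlineTree":
        tree = cls(
            branches=[
                Branch(np.asarray(b["points"]), np.asarray(b["radii"]), b.get("parent"))
                for b in d["branches"]
            ],
            source=None if d.get("source") is None else np.asarray(d["source"]),
            targets=[np.asarray(t) for t in d.get("targets", [])],
        )
        return tree

    @classmethod
    def load(cls, path) -> "CenterlineTree":
        return cls.from_dict(json.loads(Path(path).read_text()))
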