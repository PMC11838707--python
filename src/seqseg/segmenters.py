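"""Local segmentation backends.

The tracer only requires one capability: map an image patch to a
probability map on the identical grid.  Any object with a
``predict(patch) -> ProbabilityVolume`` method satisfies the contract; a
learned model is plugged in as an adapter implementing it (weight loading
and normalization are the adapter's business).

Two concrete desk-scale backends ship with the package:

* :class:`OracleSegmenter` — returns the phantom ground-truth label
  restricted to the patch cube; with corruption boxes it goes blind
  (all-zero output) inside corrupted regions, which is how the tracer's
  chance mechanism is exercised.
* :class:`ThresholdSegmenter` — Gaussian smoothing followed by a logistic
  squash of intensity around a cut value; a minimal image-driven backend.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np
from scipy import ndimage

from .errors import BackendFailure
from .volume import (
    ImageVolume,
    LabelVolume,
    NormalizationParams,
    ProbabilityVolume,
    extract_subvolume,
)

__all__ = [
    "Segmenter",
    "OracleSegmenter",
    "ThresholdSegmenter",
    "segment",
    "threshold_segmenter",
    "make_segmenter",
]


@runtime_checkable
class Segmenter(Protocol):
    """The backend contract: patch in, probability map on the same grid out."""

    def predict(self, patch: ImageVolume) -> ProbabilityVolume: ...


def segment(backend: Segmenter, patch: ImageVolume) -> ProbabilityVolume:
    """Run a backend on a patch, enforcing the output contract.

    Any backend exception is wrapped in :class:`BackendFailure`, which the
    tracer treats as a failed step (chance mechanism).
    """
    try:
        prob = backend.predict(patch)
    except Exception as exc:  # noqa: BLE001 - contract: wrap everything
        raise BackendFailure(f"{type(backend).__name__}: {exc}") from exc
    if prob.shape != patch.shape or not prob.same_grid(patch):
        raise BackendFailure(
            f"{type(backend).__name__} changed the patch grid "
            f"({patch.shape} -> {prob.shape})"
        )
    return prob


@dataclass
class OracleSegmenter:
    """Ground-truth backend for phantom experiments.

    Holds the global label volume and re-extracts it over each requested
    patch cube.  Corruption is all-or-nothing: if the patch center falls
    inside a corruption box, or corruption covers more than half of the
    patch volume, the backend returns an all-zero map — emulating a network
    that fails completely on a locally corrupted region.
    """

    label: LabelVolume
    corruption_boxes: list[tuple] = None

    def __post_init__(self) -> None:
        self.corruption_boxes = list(self.corruption_boxes or [])

    def _blinded(self, patch: ImageVolume) -> bool:
        p_lo = patch.origin
        p_hi = patch.world_max
        center = 0.5 * (p_lo + p_hi)
        for lo, hi in self.corruption_boxes:
            lo = np.asarray(lo, float)
            hi = np.asarray(hi, float)
            if np.all(center >= lo) and np.all(center <= hi):
                return True
            overlap = np.maximum(np.minimum(hi, p_hi) - np.maximum(lo, p_lo), 0.0)
            patch_vol = float(np.prod(p_hi - p_lo))
            if patch_vol > 0 and float(np.prod(overlap)) / patch_vol > 0.5:
                return True
        return False

    def predict(self, patch: ImageVolume) -> ProbabilityVolume:
        if self._blinded(patch):
            return ProbabilityVolume(
                np.zeros(patch.shape), patch.spacing.copy(), patch.origin.copy()
            )
        from .volume import SubvolumeSpec

        spec = SubvolumeSpec(
            tuple(0.5 * (patch.origin + patch.world_max)),
            float(patch.extent[0]),
            patch.shape,
        )
        lab = extract_subvolume(self.label, spec, kind="label")
        return ProbabilityVolume(
            lab.data.astype(float), patch.spacing.copy(), patch.origin.copy()
        )


@dataclass
class ThresholdSegmenter:
    """Smoothed logistic intensity thresholding.

    ``intensity_cut`` is the 50% probability level; ``smoothing_sd`` (mm)
    controls pre-smoothing; ``sharpness`` (per intensity unit) sets the
    steepness of the logistic.  Optional declared normalization is applied
    to the patch before thresholding.
    """

    intensity_cut: float
    smoothing_sd: float = 0.5
    sharpness: float = 1.0
    normalization: NormalizationParams | None = None

    def predict(self, patch: ImageVolume) -> ProbabilityVolume:
        from .volume import normalize_volume

        if self.normalization is not None:
            patch = normalize_volume(patch, self.normalization)
        data = np.asarray(patch.data, dtype=float)
        if self.smoothing_sd > 0:
            sigma_vox = self.smoothing_sd / patch.spacing
            data = ndimage.gaussian_filter(data, sigma=sigma_vox)
        z = self.sharpness * (data - self.intensity_cut)
        prob = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
        return ProbabilityVolume(prob, patch.spacing.copy(), patch.origin.copy())


def threshold_segmenter(
    patch: ImageVolume, intensity_cut: float, smoothing_sd: float = 0.5
) -> ProbabilityVolume:
    """Functional form of :class:`ThresholdSegmenter` for one-off use."""
    return ThresholdSegmenter(intensity_cut, smoothing_sd).predict(patch)


def make_segmenter(name: str, **kwargs) -> Segmenter:
    """Build a backend by config name: ``oracle``, ``threshold`` or ``external``.

    ``external`` expects a ``backend`` keyword carrying any object that
    implements the contract (e.g. an adapter around a trained network).
    """
    if name == "oracle":
        return OracleSegmenter(**kwargs)
    if name == "threshold":
        return ThresholdSegmenter(**kwargs)
    if name == "external":
        backend = kwargs.get("backend")
        if backend is None or not isinstance(backend, Segmenter):
            raise ValueError("external segmenter requires a conforming 'backend' object")
        return backend
    raise ValueError(f"unknown segmenter {name!r}")
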