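"""Axis-aligned 3D volumes: data model, normalization, resampling, patches.

Conventions used throughout the package
---------------------------------------
* World coordinates are in millimetres.
* Voxel indices are 0-based; a voxel's world position is
  ``origin + index * spacing`` (node convention), so the physical extent
  of an axis with ``n`` voxels is ``(n - 1) * spacing``.
* Only axis-aligned volumes are supported; oblique direction matrices are
  rejected at load time.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
from scipy import ndimage

from .errors import (
    InvalidSpacing,
    MissingForegroundStats,
    ObliqueOrientation,
    OutOfBounds,
    ShapeMismatch,
    ZeroVariance,
)

__all__ = [
    "ImageVolume",
    "LabelVolume",
    "ProbabilityVolume",
    "SubvolumeSpec",
    "NormalizationParams",
    "normalize_volume",
    "resample",
    "extract_subvolume",
    "read_volume",
    "write_volume",
]


@dataclass
class ImageVolume:
    """A scalar 3D grid with physical placement.

    Parameters
    ----------
    data
        3D array of intensities (arbitrary units).
    spacing
        Per-axis voxel size in mm, strictly positive.
    origin
        World position (mm) of voxel index ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.data.ndim != 3:
            raise ShapeMismatch(f"expected a 3D grid, got ndim={self.data.ndim}")
        if any(n < 2 for n in self.data.shape):
            raise ShapeMismatch(f"need >= 2 voxels per axis, got {self.data.shape}")
        if np.any(self.spacing <= 0):
            raise InvalidSpacing(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        self._validate()

    def _validate(self) -> None:  # specialized by subclasses
        pass

    # --- geometry helpers ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def extent(self) -> np.ndarray:
        """Physical length (mm) spanned by voxel centers, per axis."""
        return (np.array(self.shape) - 1) * self.spacing

    @property
    def world_max(self) -> np.ndarray:
        return self.origin + self.extent

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map world points (mm) to fractional voxel indices."""
        return (np.asarray(points, dtype=float) - self.origin) / self.spacing

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(indices, dtype=float) * self.spacing

    def contains_point(self, point: np.ndarray, tol: float = 1e-9) -> bool:
        p = np.asarray(point, dtype=float)
        return bool(np.all(p >= self.origin - tol) and np.all(p <= self.world_max + tol))

    def same_grid(self, other: "ImageVolume", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass
class LabelVolume(ImageVolume):
    """Binary ground-truth / segmentation mask sharing ImageVolume metadata."""

    def _validate(self) -> None:
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("label volume must be binary (values in {0, 1})")


@dataclass
class ProbabilityVolume(ImageVolume):
    """Per-voxel vessel probabilities in [0, 1] (segmenter output)."""

    def _validate(self) -> None:
        if self.data.min() < 0 or self.data.max() > 1:
            raise ValueError("probability volume must lie in [0, 1]")


@dataclass(frozen=True)
class SubvolumeSpec:
    """A physical cube plus the grid it is resampled onto.

    The cube spans ``[center - L/2, center + L/2]`` on every axis with
    ``L = sidelength`` (mm); the patch grid places its corner voxels on
    the cube corners (node convention).
    """

    center: tuple[float, float, float]
    sidelength: float
    grid_shape: tuple[int, int, int] = (64, 64, 64)

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        object.__setattr__(self, "grid_shape", tuple(int(n) for n in self.grid_shape))
        if self.sidelength <= 0:
            raise ValueError("sidelength must be positive")
        if any(n < 4 for n in self.grid_shape):
            raise ValueError("grid_shape must be >= 4 per axis")

    @property
    def low(self) -> np.ndarray:
        return np.asarray(self.center) - self.sidelength / 2.0

    @property
    def high(self) -> np.ndarray:
        return np.asarray(self.center) + self.sidelength / 2.0

    @property
    def patch_spacing(self) -> np.ndarray:
        return self.sidelength / (np.array(self.grid_shape) - 1.0)


@dataclass(frozen=True)
class NormalizationParams:
    """Intensity normalization policy.

    ``mr_zscore`` z-scores with the volume's own mean/sd.  ``ct_clip_fg_zscore``
    clips to ``[clip_lo, clip_hi]`` and then z-scores with foreground statistics
    (``fg_mean``, ``fg_sd``) estimated once on training data and held fixed at
    inference.
    """

    mode: Literal["mr_zscore", "ct_clip_fg_zscore"] = "mr_zscore"
    clip_lo: float = 0.0
    clip_hi: float = 1.0
    fg_mean: float | None = None
    fg_sd: float | None = None

    def __post_init__(self) -> None:
        if self.clip_lo >= self.clip_hi:
            raise ValueError("clip_lo must be < clip_hi")


def normalize_volume(volume: ImageVolume, params: NormalizationParams) -> ImageVolume:
    """Normalize intensities for a segmentation backend.

    MR mode subtracts the volume mean and divides by the volume standard
    deviation.  CT mode clips to ``[clip_lo, clip_hi]`` and applies the
    supplied fixed foreground mean/sd.
    """
    data = np.asarray(volume.data, dtype=float)
    if params.mode == "mr_zscore":
        sd = data.std()
        if sd == 0:
            raise ZeroVariance("cannot z-score a constant volume")
        out = (data - data.mean()) / sd
    elif params.mode == "ct_clip_fg_zscore":
        if params.fg_mean is None or params.fg_sd is None:
            raise MissingForegroundStats("ct mode requires fg_mean and fg_sd")
        if params.fg_sd <= 0:
            raise MissingForegroundStats("fg_sd must be positive")
        out = np.clip(data, params.clip_lo, params.clip_hi)
        out = (out - params.fg_mean) / params.fg_sd
    else:  # pragma: no cover - guarded by the dataclass literal
        raise ValueError(f"unknown normalization mode {params.mode!r}")
    return ImageVolume(out, volume.spacing.copy(), volume.origin.copy())


def resample(
    volume: ImageVolume,
    target_spacing,
    kind: Literal["image", "label"] = "image",
) -> ImageVolume:
    """Resample onto a new spacing, preserving the physical extent.

    Images use 3rd-order spline interpolation.  Labels are linearly
    interpolated per one-hot channel and re-binarized with a per-voxel
    argmax, so the output stays strictly binary.
    """
    target = np.asarray(target_spacing, dtype=float).reshape(3)
    if np.any(target <= 0):
        raise InvalidSpacing(f"target spacing must be positive, got {target}")

    if np.allclose(target, volume.spacing):
        cls = LabelVolume if kind == "label" else ImageVolume
        return cls(volume.data.copy(), volume.spacing.copy(), volume.origin.copy())

    new_shape = np.maximum(2, np.round(volume.extent / target).astype(int) + 1)
    # sample positions expressed in source index space
    grids = np.meshgrid(
        *[np.arange(n) * t / s for n, t, s in zip(new_shape, target, volume.spacing)],
        indexing="ij",
    )
    coords = np.stack(grids)
    # clamp the far edge: extent is preserved only to within one voxel
    for a in range(3):
        np.clip(coords[a], 0, volume.shape[a] - 1, out=coords[a])

    if kind == "image":
        data = ndimage.map_coordinates(
            np.asarray(volume.data, dtype=float), coords, order=3, mode="nearest"
        )
        return ImageVolume(data, target, volume.origin.copy())
    if kind == "label":
        # one-hot linear interpolation + argmax; for binary data this reduces
        # to thresholding the foreground channel at 0.5
        fg = ndimage.map_coordinates(
            np.asarray(volume.data, dtype=float), coords, order=1, mode="nearest"
        )
        data = (fg >= 0.5).astype(np.uint8)
        return LabelVolume(data, target, volume.origin.copy())
    raise ValueError(f"unknown resample kind {kind!r}")


def extract_subvolume(
    volume: ImageVolume,
    spec: SubvolumeSpec,
    kind: Literal["image", "label"] = "image",
    tol: float = 1e-6,
) -> ImageVolume:
    """Extract the physical cube of ``spec`` resampled onto its patch grid.

    Raises
    ------
    OutOfBounds
        If any part of the cube lies outside the volume extent.  The tracer
        consumes this as the image-boundary stop criterion; partial cubes
        are never zero-padded.
    """
    low, high = spec.low, spec.high
    if np.any(low < volume.origin - tol) or np.any(high > volume.world_max + tol):
        raise OutOfBounds(
            f"cube [{low}, {high}] exceeds image extent "
            f"[{volume.origin}, {volume.world_max}]"
        )
    axes = [
        low[a] + np.arange(spec.grid_shape[a]) * spec.patch_spacing[a]
        for a in range(3)
    ]
    grids = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([(grids[a] - volume.origin[a]) / volume.spacing[a] for a in range(3)])
    for a in range(3):
        np.clip(coords[a], 0, volume.shape[a] - 1, out=coords[a])

    if kind == "label":
        fg = ndimage.map_coordinates(
            np.asarray(volume.data, dtype=float), coords, order=1, mode="nearest"
        )
        data = (fg >= 0.5).astype(np.uint8)
        return LabelVolume(data, spec.patch_spacing, np.asarray(low))
    order = 3 if kind == "image" else 1
    data = ndimage.map_coordinates(
        np.asarray(volume.data, dtype=float), coords, order=order, mode="nearest"
    )
    return ImageVolume(data, spec.patch_spacing, np.asarray(low))


# --- I/O ---------------------------------------------------------------------

def _check_axis_aligned(direction: np.ndarray, path) -> None:
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise ObliqueOrientation(
            f"{path}: only axis-aligned volumes are supported "
            f"(direction matrix {direction.tolist()})"
        )


def read_volume(path, kind: Literal["image", "label"] = "image") -> ImageVolume:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) volume.

    Spacing and origin are taken from the header; the direction matrix must
    be the identity (axis-aligned).
    """
    path = Path(path)
    if path.suffix in (".mha", ".mhd"):
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        direction = np.asarray(img.GetDirection()).reshape(3, 3)
        _check_axis_aligned(direction, path)
        # SimpleITK returns (z, y, x); transpose into our (x, y, z) layout
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        spacing = np.asarray(img.GetSpacing())
        origin = np.asarray(img.GetOrigin())
    else:
        import nibabel as nib

        img = nib.load(str(path))
        affine = img.affine
        _check_axis_aligned(np.sign(affine[:3, :3]) * (affine[:3, :3] != 0), path)
        spacing = np.abs(np.diag(affine[:3, :3]))
        if np.any(spacing == 0) or np.count_nonzero(affine[:3, :3]) != 3:
            raise ObliqueOrientation(f"{path}: affine is not diagonal")
        if np.any(np.diag(affine[:3, :3]) < 0):
            raise ObliqueOrientation(f"{path}: negative-direction affine not supported")
        data = np.asanyarray(img.dataobj)
        origin = affine[:3, 3]
    cls = LabelVolume if kind == "label" else ImageVolume
    if kind == "label":
        data = (np.asarray(data) > 0.5).astype(np.uint8)
    return cls(np.asarray(data), spacing, origin)


def write_volume(volume: ImageVolume, path) -> None:
    """Write a volume as NIfTI or MetaImage depending on the file suffix."""
    path = Path(path)
    if path.suffix in (".mha", ".mhd"):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(volume.data.transpose(2, 1, 0)))
        img.SetSpacing(tuple(volume.spacing))
        img.SetOrigin(tuple(volume.origin))
        sitk.WriteImage(img, str(path))
    else:
        import nibabel as nib

        affine = np.eye(4)
        affine[:3, :3] = np.diag(volume.spacing)
        affine[:3, 3] = volume.origin
        nib.save(nib.Nifti1Image(np.asarray(volume.data), affine), str(path))
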