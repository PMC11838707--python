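"""Exception hierarchy.

Several of these are not "errors" so much as signals the tracer consumes:
``OutOfBounds`` is the image-boundary stop criterion, and ``NoSurface`` /
``InsufficientOutlets`` / ``CenterlineFailure`` / ``BackendFailure`` each
trigger a chance step.
"""


class SeqSegError(Exception):
    """Base class for all package exceptions."""


# --- volume / grid errors ---------------------------------------------------

class ZeroVariance(SeqSegError):
    """z-scoring requested on a volume with zero intensity variance."""


class MissingForegroundStats(SeqSegError):
    """CT-style normalization without the required foreground mean/sd."""


class InvalidSpacing(SeqSegError):
    """Non-positive voxel spacing."""


class OutOfBounds(SeqSegError):
    """A requested physical cube extends past the global image extent.

    The tracer interprets this as "reached the image boundary" and
    terminates the current branch.
    """


class GridMismatch(SeqSegError):
    """Two grids that must match (shape/spacing/origin) do not."""


class ShapeMismatch(SeqSegError):
    """Array shapes differ where identical shapes are required."""


class ObliqueOrientation(SeqSegError):
    """Volume on disk carries a non-axis-aligned direction matrix."""


# --- phantom ----------------------------------------------------------------

class InvalidGeometry(SeqSegError):
    """Inconsistent synthetic-tree geometry (e.g. child wider than parent)."""


class TreeOutOfGrid(SeqSegError):
    """A synthetic tube exits the phantom volume."""


# --- sampling ---------------------------------------------------------------

class DegenerateTangent(SeqSegError):
    """Cannot build a perpendicular frame from a (near-)zero tangent."""


class EmptyDataset(SeqSegError):
    """Patch sampling produced no usable pairs."""


# --- segmentation backends --------------------------------------------------

class BackendFailure(SeqSegError):
    """Wraps any exception raised by a segmentation backend."""


# --- geometry ---------------------------------------------------------------

class NoSurface(SeqSegError):
    """The iso-level set of a probability patch is empty."""


class InsufficientOutlets(SeqSegError):
    """Fewer than two truncation boundaries found; roles cannot be assigned."""


class CenterlineFailure(SeqSegError):
    """Wave propagation could not connect a target to the source."""


# --- tracer -----------------------------------------------------------------

class ChancesExhausted(SeqSegError):
    """Consecutive-failure budget spent; the branch terminates."""


class SeedOutsideImage(SeqSegError):
    """The user seed point is not inside the global image."""


class SeedSegmentationFailure(SeqSegError):
    """Even the very first subvolume produced no vessel surface."""


# --- assembly / metrics -----------------------------------------------------

class EmptySegmentation(SeqSegError):
    """No voxel exceeds the assembly threshold."""


class EmptySet(SeqSegError):
    """A set-distance metric received an empty voxel set."""


class EmptyCenterline(SeqSegError):
    """A centerline metric received a tree with no length."""
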