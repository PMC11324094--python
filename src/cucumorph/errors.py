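"""Exception hierarchy for the cucumorph pipeline.

Every stage raises a subclass of :class:`CucumorphError` so batch runners can
catch one type, record an error row, and continue with the next image.
"""


class CucumorphError(Exception):
    """Base class for all pipeline errors."""


class InvalidImageError(CucumorphError):
    """Input raster is not a valid 8-bit RGB (or grayscale) image."""


class NoObjectError(CucumorphError):
    """Foreground vanished: nothing left after thresholding/cleanup."""


class MissingReferenceError(CucumorphError):
    """Fewer than two objects in the scene and no single-object fallback."""


class AmbiguousSceneError(CucumorphError):
    """Card and fruit cannot be told apart (rectangularities too close)."""


class GeometryError(CucumorphError):
    """Degenerate geometry (zero-area rectangle, coincident endpoints, ...)."""


class ConfigError(CucumorphError):
    """Invalid or missing configuration value."""


class SkeletonTopologyError(CucumorphError):
    """Skeleton has no usable endpoint pair (loop, single pixel, empty)."""


class DegenerateSkeletonError(CucumorphError):
    """Too few skeleton points survive subsampling for smoothing."""


class ExtensionFailureError(CucumorphError):
    """Centerline extrapolation diverged before reaching the contour."""


class SegmentationFailureError(CucumorphError):
    """Fruit could not be partitioned (both halves degenerate, empty body)."""


class ModelUnavailableError(CucumorphError):
    """Stage-3 shape classification requested but no six-class model given."""


class SpecificationError(CucumorphError):
    """Synthetic-fruit spec is geometrically impossible."""
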