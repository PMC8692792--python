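"""Exception hierarchy.

Every error a caller can act on derives from :class:`LungmorphError`;
configuration mistakes additionally derive from :class:`ValueError` so that
plain ``except ValueError`` in driver scripts keeps working.
"""


class LungmorphError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(LungmorphError, ValueError):
    """A parameter violates a documented invariant (bad value, bad window...)."""


class MetadataError(LungmorphError):
    """Required volume metadata (voxel spacing, axis labels) is missing."""


class UnsupportedInputError(LungmorphError):
    """Input is readable but outside the supported model (e.g. anisotropic)."""


class SegmentationError(LungmorphError):
    """Thresholding is impossible (e.g. constant-intensity volume)."""


class PlacementError(LungmorphError):
    """RVE placement could not satisfy the request within the retry budget."""


class GridMismatchError(LungmorphError):
    """Two gridded objects that must share shape/spacing/kernel do not."""


class DegenerateInputError(LungmorphError):
    """Statistical input with zero within-group variance but unequal means."""


class InsufficientSampleError(LungmorphError):
    """Sample too small for the requested test's validity floor."""


class MissingInputError(LungmorphError):
    """A pipeline stage was invoked before its upstream artifact exists."""
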