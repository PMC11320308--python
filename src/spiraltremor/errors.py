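"""Exception hierarchy shared across the pipeline.

Every error raised by this package derives from :class:`SpiralToolError`
so callers (and the CLI) can catch pipeline failures in one place while
still distinguishing the step that failed.
"""


class SpiralToolError(Exception):
    """Base class for all errors raised by spiraltremor."""


class DegeneratePointError(SpiralToolError):
    """A point coincides with the spiral origin; its polar angle is undefined."""


class DegenerateFitError(SpiralToolError):
    """The two fit points cannot determine a spiral (equal radii or angles)."""


class InvalidSelectionError(SpiralToolError):
    """The two-point fit produced a non-positive spiral scale b."""


class OutOfDomainError(SpiralToolError):
    """An angle outside the spiral's domain (theta <= -theta_r, or phi < 0)."""


class ImageReadError(SpiralToolError):
    """A raster file could not be read or decoded."""


class EmptyImageError(SpiralToolError):
    """No pixel above the density floor; nothing to flatten."""


class CropError(SpiralToolError):
    """A crop rectangle does not intersect the flattened grid."""


class NoSignalError(SpiralToolError):
    """Profile extraction found no column with ink."""


class EmptySignalError(SpiralToolError):
    """A noise crop removed every sample."""


class DegenerateSignalError(SpiralToolError):
    """The extracted profile is constant; it cannot be normalized."""


class NoPeakError(SpiralToolError):
    """The spectrum carries no energy inside the tremor band of interest."""


class ValidationError(SpiralToolError):
    """A configuration or parameter value is out of its allowed range."""
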