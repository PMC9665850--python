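"""Exception hierarchy.

Every error raised by the package derives from :class:`NetquantError` so
callers (and the CLI) can catch pipeline failures in one place.
"""


class NetquantError(Exception):
    """Base class for all package errors."""


class DimensionError(NetquantError):
    """Rasters that must share a shape do not."""


class FormatError(NetquantError):
    """Unsupported pixel format (float samples, RGB, ...)."""


class ConfigurationError(NetquantError):
    """Invalid or incomplete run configuration."""


class ParameterError(NetquantError):
    """An operation parameter is out of its valid range."""


class UndefinedResultError(NetquantError):
    """The requested statistic is undefined for this input (e.g. 0/0 %NETs)."""


class DegenerateNormalizationError(UndefinedResultError):
    """A time-course series carries no signal to normalize against."""


class StateError(NetquantError):
    """An operation was called before a required preceding step."""


class DensityError(NetquantError):
    """Synthetic objects cannot be placed at the requested density."""
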