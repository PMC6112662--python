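"""Exception types raised across the pipeline."""


class StonebeamError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(StonebeamError, ValueError):
    """A parameter violates its documented domain (non-positive width, bad lag band, ...)."""


class ConfigurationError(StonebeamError, ValueError):
    """An acquisition or pipeline configuration is inconsistent (e.g. fs < 4*f0)."""


class OutOfBoundsError(StonebeamError, ValueError):
    """A scene, pixel or focus lies outside the imaged region."""


class PatchTruncationError(StonebeamError, ValueError):
    """A requested pixel needs samples beyond the recorded trace."""


class UndefinedMetricError(StonebeamError, ValueError):
    """A ROI metric is undefined for the given statistics (zero mean/variance)."""


class InsufficientAnglesError(StonebeamError, ValueError):
    """An operation needs more plane-wave transmissions than the data holds."""


class EmptyDetectionError(StonebeamError, ValueError):
    """No pixel exceeded the sizing threshold inside the search region."""


class DegenerateSegmentationError(StonebeamError, ValueError):
    """The image cannot be split into the requested intensity classes."""
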