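"""Exception hierarchy.

Data-quality problems (``NoSignalError``, ``DegenerateSignalError``) are kept
distinct from caller mistakes (``InvalidParameterError``) and from pacing
protocol violations so that batch drivers can triage failures.
"""


class SpiralMapError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(SpiralMapError, ValueError):
    """A parameter is outside its documented domain."""


class GeometryError(SpiralMapError):
    """A pattern does not fit the raster, or a coordinate is off the path."""


class NoSignalError(SpiralMapError):
    """No detectable action potential / wave in the data."""


class DegenerateSignalError(SpiralMapError):
    """Signal exists but is degenerate (zero mean, constant, singular fit)."""


class PairingError(SpiralMapError):
    """Simultaneous traces could not be paired beat-by-beat."""


class ProtocolViolationError(SpiralMapError):
    """A pacing scan violates its protocol (e.g. capture after loss)."""


class FormatError(SpiralMapError):
    """A file is truncated, missing metadata, or otherwise unreadable."""
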