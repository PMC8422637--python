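"""Exception hierarchy.

Every error raised by the library derives from :class:`UnetqError` so the CLI
can distinguish data problems (exit 3) from usage problems (exit 2, click).
"""


class UnetqError(Exception):
    """Base class for all library errors."""


class ShapeError(UnetqError):
    """Tensor shapes inconsistent with a layer or operation."""


class GraphError(UnetqError):
    """Structural problem in a network graph."""


class ArchiveError(UnetqError):
    """Malformed, corrupt or unreadable network archive."""


class QuantizationError(UnetqError):
    """Invalid input to a quantization operation (e.g. non-finite values)."""


class CalibrationError(UnetqError):
    """Invalid calibration request (e.g. empty calibration set)."""


class AccumulatorOverflow(UnetqError):
    """An int8 dot product exceeded the 32-bit signed accumulator range."""


class PartitionError(UnetqError):
    """A layer cannot be partitioned under the given resource constraints."""


class FitError(UnetqError):
    """The toy fitting helper failed to reach the requested quality floor."""
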