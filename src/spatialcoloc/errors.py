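"""Exception hierarchy shared across modules."""


class SpatialcolocError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SpatialcolocError, ValueError):
    """Invalid argument or malformed input file."""


class DegenerateSetError(SpatialcolocError):
    """Gene set whose complement within the measured genes is empty."""


class GeneSetNotMeasuredError(SpatialcolocError):
    """Gene set with no overlap with the measured genes."""


class DegenerateNullError(SpatialcolocError):
    """Join-count null with zero variance or a single label class.

    Carries the null mean/sd when they were computable so callers can
    surface a not-computable result instead of a silent zero.
    """

    def __init__(self, message, null_mean=None, null_sd=None):
        super().__init__(message)
        self.null_mean = null_mean
        self.null_sd = null_sd


class DegenerateHistogramError(SpatialcolocError):
    """Constant image offered to an automatic histogram threshold."""
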