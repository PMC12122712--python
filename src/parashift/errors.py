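"""Exception hierarchy for parashift.

Every error raised on purpose derives from :class:`ParashiftError`, so callers
(and the CLI) can distinguish pipeline failures from programming bugs.
"""


class ParashiftError(Exception):
    """Base class for all parashift errors."""


class ConfigurationError(ParashiftError):
    """Inconsistent or non-conformable configuration (grids, extents, layers)."""


class FormatError(ParashiftError):
    """A file does not conform to its expected format."""


class DegenerateInputError(ParashiftError):
    """Input is formally valid but carries no usable information
    (e.g. all-zero sampling weights, no valid cells)."""


class InsufficientDataError(ParashiftError):
    """Too few records to perform the requested operation."""


class ConvergenceError(ParashiftError):
    """Optimizer failed to converge; carries the final gradient norm."""

    def __init__(self, message: str, gradient_norm: float):
        super().__init__(message)
        self.gradient_norm = gradient_norm


class IrreducibleCollinearityError(ParashiftError):
    """Two protected predictors are collinear above the threshold; no valid
    retained set exists that keeps both."""
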