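"""Exception hierarchy for dopsig.

Every error raised by the library derives from :class:`DopsigError`, so
callers can catch one base class. Parameter-validation failures also derive
from :class:`ValueError` for interoperability with generic code.
"""


class DopsigError(Exception):
    """Base class for all dopsig errors."""


class InvalidParameterError(DopsigError, ValueError):
    """A parameter violates its documented precondition."""


class DegenerateFitError(DopsigError):
    """A regression cannot be computed (e.g. constant regressor)."""


class DegenerateTraceError(DopsigError):
    """A trace has zero variance where positive variance is required."""


class UnusableBaselineError(DopsigError):
    """The fitted reference is non-positive somewhere; dFF is undefined."""

    def __init__(self, message: str, first_offending_time_s: float | None = None):
        super().__init__(message)
        self.first_offending_time_s = first_offending_time_s


class EmptyAlignmentError(DopsigError):
    """No usable events remain after alignment."""


class InvalidWindowError(DopsigError):
    """A requested analysis window lies outside the available data."""


class ConfigurationError(DopsigError):
    """An event type or option cannot be resolved to a configuration."""


class InsufficientDataError(DopsigError):
    """Too few observations for the requested statistic."""


class NoTransientError(DopsigError):
    """No transient rises above the detection criterion."""


class FitFailureError(DopsigError):
    """Nonlinear fit failed to converge; diagnostics in the message."""


class AlreadyCalibratedError(DopsigError):
    """Trace is already in concentration units; refusing to rescale."""


class InsufficientSweepsError(DopsigError):
    """Fewer sweeps than the session-summary policy requires."""


class ScheduleMismatchError(DopsigError):
    """A metric was requested for the wrong operant schedule."""
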