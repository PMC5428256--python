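"""Exception hierarchy for uroflow.

All errors raised by the library derive from :class:`UroflowError` so callers
can catch library failures without masking programming errors.
"""


class UroflowError(Exception):
    """Base class for all uroflow errors."""


class ConfigurationError(UroflowError, ValueError):
    """A configuration object violates its invariants."""


class InputError(UroflowError, ValueError):
    """Malformed input data (unsorted times, missing columns, ...)."""


class InsufficientDataError(UroflowError, ValueError):
    """Too few observations for the requested fit."""


class DegenerateDesignError(UroflowError, ValueError):
    """The design matrix is singular or a covariate has no variation."""


class ConvergenceError(UroflowError, RuntimeError):
    """An iterative procedure failed to converge.

    Carries the trace of iterates so the failure can be diagnosed.
    """

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = list(trace) if trace is not None else []
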