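"""Package-wide exception types."""


class ConfigurationError(ValueError):
    """A required column, option or coefficient is missing or malformed."""


class ValidationError(ValueError):
    """Input data violate a structural invariant (bad row, bad height, ...)."""


class ConvergenceError(RuntimeError):
    """An iterative fit failed to converge.

    Attributes
    ----------
    trace : list
        Objective values (or parameter snapshots) recorded per iteration.
    best : object
        Best iterate reached before failure, when available.
    """

    def __init__(self, message, trace=None, best=None):
        super().__init__(message)
        self.trace = trace if trace is not None else []
        self.best = best
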