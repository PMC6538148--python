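"""Exception hierarchy shared across the pipeline."""


class GliogrowError(Exception):
    """Base class for all package errors."""


class InvalidInputError(GliogrowError, ValueError):
    """An argument violates a documented precondition."""


class FitConvergenceError(GliogrowError):
    """Nonlinear fit failed to converge from every starting point.

    Carries the best (lowest-sse) candidate found so callers can inspect it.
    """

    def __init__(self, message: str, best_candidate=None):
        super().__init__(message)
        self.best_candidate = best_candidate


class TableFormatError(GliogrowError):
    """A tabular input failed validation; ``issues`` lists row-level messages."""

    def __init__(self, issues):
        self.issues = list(issues)
        super().__init__("invalid volume table:\n" + "\n".join(self.issues))
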