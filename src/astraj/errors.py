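"""Exception hierarchy.

Every error the library raises deliberately derives from
:class:`AstrajError`, so callers (and the CLI exit-code mapping) can
distinguish misuse from numerical failure.
"""


class AstrajError(Exception):
    """Base class for all deliberate errors."""


class InvalidInputError(AstrajError, ValueError):
    """Arguments violate a documented precondition."""


class UndefinedMetricError(AstrajError):
    """The requested metric is undefined on this input
    (e.g. AUROC with a single class, silhouette with k=1)."""


class ConvergenceError(AstrajError):
    """A numerical routine failed to reach its tolerance.

    Carries the final residuals when available.
    """

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals


class DegenerateModelError(AstrajError):
    """A model cannot be fit on this data (e.g. no events)."""


class ConfigError(AstrajError):
    """Run configuration is malformed (unknown keys, bad types)."""


class DataError(AstrajError):
    """Input table is missing required columns or malformed."""
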