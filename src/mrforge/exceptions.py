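"""Exception hierarchy for mrforge.

All package errors derive from :class:`MRForgeError` so callers can catch
one base class; subclasses distinguish configuration mistakes from bad
input data and from numerically degenerate problems.
"""


class MRForgeError(Exception):
    """Base class for all mrforge errors."""


class ConfigurationError(MRForgeError):
    """A configuration value (column map, threshold, option) is invalid."""


class InputError(MRForgeError):
    """Input data violates a precondition (empty file, duplicate SNP, ...)."""


class InsufficientInstrumentsError(InputError):
    """Fewer instruments than the estimator's minimum."""


class DegenerateInstrumentError(InputError):
    """A per-SNP computation is undefined (e.g. zero exposure effect)."""


class RankDeficiencyError(InputError):
    """Multivariable design matrix is rank deficient.

    Carries the names of the offending collinear exposure columns in
    ``columns`` when they can be identified.
    """

    def __init__(self, message: str, columns: tuple = ()):  # noqa: D401
        super().__init__(message)
        self.columns = tuple(columns)


class ConvergenceError(MRForgeError):
    """An iterative solver failed to converge; ``trace`` holds the iterates."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace
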