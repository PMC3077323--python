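"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ConfigurationError/ValidationError -> 2,
AnalysisError (and subclasses) -> 3.
"""


class TrialConsistError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TrialConsistError):
    """Bad user configuration: missing columns, unknown names, invalid knobs."""


class ValidationError(TrialConsistError):
    """Input data violate an invariant (e.g. LFS time after OS time)."""


class AnalysisError(TrialConsistError):
    """An analysis cannot be carried out on the given data."""


class EstimationError(AnalysisError):
    """A model fit is impossible (no events, an empty arm, ...)."""


class MonotoneLikelihoodError(EstimationError):
    """The Cox partial likelihood is monotone: the effect estimate diverges.

    ``direction`` is +1 when the (oriented) log hazard ratio diverges to
    +infinity and -1 otherwise.
    """

    def __init__(self, message: str, direction: int):
        super().__init__(message)
        self.direction = direction
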