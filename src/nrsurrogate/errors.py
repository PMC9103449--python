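"""Exception hierarchy.

Every distinct failure mode named in the data contracts gets its own class so
callers can catch precisely; all inherit from :class:`NRSurrogateError`.
"""


class NRSurrogateError(Exception):
    """Base class for all package errors."""


class TableReadError(NRSurrogateError):
    """Input file missing or unreadable."""


class NonNumericDataError(NRSurrogateError):
    """A body cell of the CSV could not be parsed as a number."""


class MissingTargetError(NRSurrogateError):
    """A target column was required but absent (or requested but not found)."""


class InvalidTableError(NRSurrogateError):
    """A FeatureTable invariant is violated (NaN, shape mismatch, empty)."""


class InvalidSpecError(NRSurrogateError):
    """A configuration/spec field is out of its allowed range."""


class NegativeFeatureMeanError(NRSurrogateError):
    """NNI variance rule needs nonnegative feature means; one was negative."""


class EmptyClusterError(NRSurrogateError):
    """A cluster required by an operation has no members."""


class ConstantTargetError(NRSurrogateError):
    """R^2 is undefined: the observed values have zero variance."""


class ZeroSpreadError(NRSurrogateError):
    """Coverage is undefined: sd of the absolute observed values is zero."""


class FoldSizeError(NRSurrogateError):
    """Cross-validation folds would have fewer than two test rows."""


class StageError(NRSurrogateError):
    """A pipeline stage failed; the stage name is part of the message."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
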