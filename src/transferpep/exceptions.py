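"""Exception hierarchy shared across the package."""


class TransferPepError(Exception):
    """Base class for all package-specific errors."""


class FormatError(TransferPepError):
    """A file does not conform to the expected tabular exchange format."""


class ValidationError(TransferPepError):
    """An object violates one of its declared invariants."""


class InsufficientDataError(TransferPepError):
    """Too few records to run an estimator.

    Carries ``count`` (what was available) and ``required`` where known.
    """

    def __init__(self, message: str, count: int | None = None,
                 required: int | None = None):
        super().__init__(message)
        self.count = count
        self.required = required


class DegenerateWeightsError(TransferPepError):
    """All kernel weights are (numerically) zero."""


class EstimationError(TransferPepError):
    """An estimation step cannot proceed on the given data."""


class ModelInconsistencyError(TransferPepError):
    """Fitted components contradict each other (e.g. a null mass > 1)."""
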