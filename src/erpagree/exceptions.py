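"""Exception hierarchy for erpagree."""


class ErpAgreeError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(ErpAgreeError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(ErpAgreeError):
    """A detection container or CSV does not match the expected layout."""


class ZoneConstructionError(ErpAgreeError):
    """No admissible extremum was found when placing a fuzzy zone.

    Raised when the average ERP lacks an identifiable peak of the required
    polarity inside the search window; callers may supply manual centers.
    """


class RegressorConstructionError(ErpAgreeError):
    """A supplied peak latency falls on a segment of the wrong polarity."""


class FitError(ErpAgreeError):
    """The least-squares design matrix is rank deficient."""


class InsufficientDataError(ErpAgreeError):
    """Too few paired observations to compute the requested index."""
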