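"""Exception hierarchy shared across the package."""


class ActigateError(Exception):
    """Base class for all package errors."""


class FormatError(ActigateError):
    """A session file's header or layout is malformed."""


class ValidationError(ActigateError):
    """A data structure violates one of its invariants."""


class CalibrationError(ActigateError):
    """Rest and effort recordings are not separable.

    Carries the rest/effort percentile statistics so the caller can report
    how close the two recordings were.
    """

    def __init__(self, message: str, rest_stat: float, effort_stat: float):
        super().__init__(message)
        self.rest_stat = rest_stat
        self.effort_stat = effort_stat
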