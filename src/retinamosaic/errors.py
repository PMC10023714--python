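"""Exception hierarchy.

All data-dependent failures derive from :class:`RetinaMosaicError` so callers
(and the CLI) can distinguish bad input from programming errors.
"""


class RetinaMosaicError(Exception):
    """Base class for all package errors."""


class GeometryError(RetinaMosaicError):
    """Invalid polygon, point outside window, ROI outside image, etc."""


class ParameterError(RetinaMosaicError):
    """A numeric parameter violates its precondition."""


class PackingError(RetinaMosaicError):
    """Dart-throwing exhausted its attempt budget before placing all points."""


class InsufficientPointsError(RetinaMosaicError):
    """A statistic was requested on a pattern with too few points."""


class UndefinedZoneError(RetinaMosaicError):
    """Exclusion-zone estimation on a degenerate (all-zero) profile."""


class SWCParseError(RetinaMosaicError):
    """Malformed SWC morphology file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
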