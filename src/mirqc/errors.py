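"""Exception hierarchy shared across the pipeline."""


class MirqcError(Exception):
    """Base class for all errors raised by mirqc."""


class FormatError(MirqcError):
    """A required column or field is missing from an input table."""


class ParseError(MirqcError):
    """A cell could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class ConfigurationError(MirqcError):
    """Inconsistent or incomplete run configuration."""


class InsufficientPointsError(MirqcError):
    """Too few determined dilution points to fit a curve."""


class InsufficientDataError(MirqcError):
    """Too few complete pairs / subjects for a statistic."""


class ZeroVarianceError(MirqcError):
    """A statistic is undefined on a constant vector or matrix."""
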