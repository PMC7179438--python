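"""Structured exceptions raised across the package."""


class QsarError(Exception):
    """Base class for all package-specific errors."""


class TableFormatError(QsarError):
    """A compound table failed structural validation (duplicate ids,
    non-numeric cells, missing columns, empty input)."""


class InvalidValueError(QsarError, ValueError):
    """A scalar input violated a precondition (non-positive EC50,
    negative feature count, out-of-range angle, ...)."""


class FitError(QsarError):
    """A regression could not be fitted (rank deficiency, too few rows,
    constant activity)."""
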