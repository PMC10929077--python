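"""Exception hierarchy used across methylqc."""


class MethylQCError(Exception):
    """Base class for all methylqc errors."""


class InvalidParameterError(MethylQCError, ValueError):
    """A configuration or function parameter is outside its valid range."""


class InvalidInputError(MethylQCError, ValueError):
    """Input data violates a precondition (unsorted, non-finite, mixed keys...)."""


class FormatError(MethylQCError, ValueError):
    """A file does not conform to the expected dialect.

    ``column`` and ``line`` carry the offending column name / 1-based line
    number when known.
    """

    def __init__(self, message: str, *, column: str | None = None,
                 line: int | None = None):
        super().__init__(message)
        self.column = column
        self.line = line


class InsufficientDataError(MethylQCError, ValueError):
    """Too few observations to compute the requested statistic."""


class UndefinedResultError(MethylQCError, ValueError):
    """The statistic is undefined on this input (e.g. no unambiguous reads)."""


class UndefinedCorrelationError(UndefinedResultError):
    """Pearson correlation undefined because one vector has zero variance."""
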