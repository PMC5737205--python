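"""Exception types shared across the package."""


class BioqueryError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BioqueryError):
    """Invalid or missing configuration (unknown repository, bad schema)."""


class MalformedRecordError(BioqueryError):
    """A source document violates the record contract (e.g. missing DocID)."""


class ParseError(BioqueryError):
    """A qrels/run/lexicon file line could not be parsed."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class UndefinedStatisticsError(BioqueryError):
    """A collection statistic is requested from an empty index."""
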