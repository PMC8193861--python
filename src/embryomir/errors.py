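"""Exception hierarchy shared by all embryomir modules."""


class EmbryomirError(Exception):
    """Base class for all package errors."""


class FormatError(EmbryomirError):
    """A file does not match the expected tabular layout (e.g. missing column)."""


class RowParseError(FormatError):
    """A data row could not be parsed; carries the zero-based row index."""

    def __init__(self, message: str, row: int):
        super().__init__(f"row {row}: {message}")
        self.row = row


class IntegrityError(EmbryomirError):
    """Duplicate keys or mismatched target sets in joined tables."""


class ValidationError(EmbryomirError):
    """A value violates a domain invariant (unknown sample type, bad fraction...)."""


class ConfigurationError(EmbryomirError):
    """An invalid analysis or simulation configuration."""


class UsageError(EmbryomirError):
    """An operation was called with arguments outside its contract."""


class AnalysisError(EmbryomirError):
    """A computation cannot proceed (e.g. censored reference assay)."""


class UndefinedFractionError(AnalysisError):
    """Extracellular fraction undefined: target undetected in the cohort lysate."""
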