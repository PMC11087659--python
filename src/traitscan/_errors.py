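"""Exception hierarchy shared across the package."""


class TraitScanError(Exception):
    """Base class for all package errors."""

    category = "error"


class FormatError(TraitScanError):
    """Malformed input file (missing columns, unparseable values)."""

    category = "format"


class ValidationError(TraitScanError):
    """Input parsed but violates a content constraint."""

    category = "validation"


class InsufficientDataError(TraitScanError):
    """Not enough observations to carry out an estimate."""

    category = "insufficient_data"


class DomainError(TraitScanError, ValueError):
    """Argument outside its mathematical domain."""

    category = "domain"


class MissingVariantError(TraitScanError, LookupError):
    """Requested variants absent from a panel or summary file."""

    category = "lookup"

    def __init__(self, missing, message=None):
        self.missing = list(missing)
        super().__init__(message or f"variants not found: {', '.join(self.missing)}")


class DegenerateStatisticError(TraitScanError):
    """A derived statistic is numerically meaningless (e.g. negative residual variance)."""

    category = "degenerate"
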