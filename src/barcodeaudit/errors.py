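"""Exception hierarchy for the barcode-audit pipeline."""


class BarcodeAuditError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(BarcodeAuditError):
    """A sequence or table file could not be parsed."""


class SchemaError(BarcodeAuditError):
    """A metadata table is missing required columns."""


class ValidationError(BarcodeAuditError):
    """Input records violate a library invariant (e.g. duplicate ids)."""


class JoinError(BarcodeAuditError):
    """Sequences and metadata could not be joined one-to-one."""


class InsufficientOverlapError(BarcodeAuditError):
    """A sequence pair shares fewer unambiguous sites than ``min_overlap``."""


class ConfigError(BarcodeAuditError):
    """A run configuration is internally inconsistent."""
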