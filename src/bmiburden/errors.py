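"""Exception hierarchy shared across the pipeline stages."""


class BmiBurdenError(Exception):
    """Base class for all package errors."""


class ConfigError(BmiBurdenError, ValueError):
    """A configuration field is missing, ill-typed, or out of range."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field {field!r}: {message}")


class DomainError(BmiBurdenError, ValueError):
    """An argument is outside the mathematically valid domain."""


class SchemaError(BmiBurdenError, ValueError):
    """A table is missing required rows/columns or violates a range constraint."""


class AlignmentError(BmiBurdenError, ValueError):
    """Two draw matrices do not share keys or draw counts."""


class EstimationError(BmiBurdenError, RuntimeError):
    """A model cannot be estimated from the data provided (e.g. empty cells)."""


class ConvergenceError(BmiBurdenError, RuntimeError):
    """An iterative fit failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)
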