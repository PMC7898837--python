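"""Exception hierarchy for relmediate."""


class RelmediateError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(RelmediateError):
    """A delimited-text input does not match its declared column schema."""


class ValidationError(RelmediateError):
    """Input data violate an invariant (negative rate, gap in age bands, ...)."""


class ConfigurationError(RelmediateError):
    """A request is inconsistent with the configured objects (e.g. asking a
    stratified lookup of an unstratified lifetable)."""


class DomainError(RelmediateError):
    """An argument is outside the mathematical domain of an operation."""


class ConvergenceError(RelmediateError):
    """An iterative fit failed to converge; carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class RankDeficiencyError(RelmediateError):
    """The design matrix is rank deficient; names the collinear columns."""

    def __init__(self, message, columns=None):
        super().__init__(message)
        self.columns = list(columns or [])
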