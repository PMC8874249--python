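"""Exception hierarchy shared across the pipeline."""


class QivivError(Exception):
    """Base class for all package errors."""


class SchemaError(QivivError):
    """A required field or parameter is missing or malformed."""


class DomainError(QivivError, ValueError):
    """A value violates its physical/statistical domain."""


class NumericalError(QivivError):
    """Solver failure or loss of numerical integrity."""


class ConfigError(QivivError):
    """Invalid or unknown configuration option."""


class BracketingError(QivivError):
    """A sampling range does not bracket the requested target."""
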