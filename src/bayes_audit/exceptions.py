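"""Exception hierarchy for the audit toolkit.

All toolkit errors derive from :class:`AuditError` so callers can catch one
base class; the CLI maps subclasses onto distinct exit codes (validation
failures exit 2, numerical failures exit 3).
"""


class AuditError(Exception):
    """Base class for all errors raised by this package."""


class DomainError(AuditError, ValueError):
    """An input value lies outside its mathematical domain."""


class ConfigurationError(AuditError, ValueError):
    """A config file, CLI invocation or dispatch request is malformed."""


class NumericalError(AuditError, ArithmeticError):
    """A numerical routine failed to reach its requested tolerance."""


class ContractError(AuditError, RuntimeError):
    """An operation was called in a way that violates its usage contract."""
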