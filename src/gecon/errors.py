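"""Exception hierarchy shared across the package."""


class GeconError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(GeconError, ValueError):
    """Input data violates a container invariant (shape, finiteness, uniqueness)."""


class ParseError(GeconError, ValueError):
    """A text input file could not be parsed; message locates the offending cell/line."""


class ParameterError(GeconError, ValueError):
    """A tunable parameter is outside its admissible range."""


class ReconciliationError(GeconError, ValueError):
    """Gene identifiers of two objects cannot be reconciled; message lists offenders."""


class ContractError(GeconError, RuntimeError):
    """An operation was called outside its stated precondition."""
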