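"""Exception hierarchy shared across the package."""


class OrderStatesError(Exception):
    """Base class for all package errors."""


class ParameterError(OrderStatesError, ValueError):
    """A model or operation received invalid (e.g. non-finite) parameters."""


class ConfigurationError(OrderStatesError, ValueError):
    """A run/simulation configuration is inconsistent or unknown."""


class ContractError(OrderStatesError, ValueError):
    """An operation was called outside its contract (shape/label mismatch, empty input)."""


class FormatError(OrderStatesError, ValueError):
    """An input matrix or file violates its format contract."""


class DegenerateLikelihoodError(OrderStatesError, ArithmeticError):
    """The likelihood is degenerate: zero noise with data inconsistent with it."""
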