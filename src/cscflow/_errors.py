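"""Exception hierarchy shared across the package."""


class CscflowError(Exception):
    """Base class for all package-specific errors."""


class DomainError(CscflowError, ValueError):
    """An argument lies outside its mathematical domain."""


class ContractError(CscflowError, ValueError):
    """A vector has the wrong length or a model contract is violated."""


class DegenerateSpecError(DomainError):
    """A parameter specification resolves to a zero-width interval."""


class FormatError(CscflowError, ValueError):
    """A file does not match the expected on-disk format."""


class SingularityError(CscflowError, ValueError):
    """A regression design is rank-deficient (collinear columns)."""


class UnknownModelError(CscflowError, KeyError):
    """Requested model name is not in the registry."""


class ConfigError(CscflowError, ValueError):
    """An experiment configuration failed validation."""
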