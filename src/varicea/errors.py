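"""Exception types shared across the package."""


class VariceaError(Exception):
    """Base class for all package errors."""


class ConfigError(VariceaError):
    """A parameter document is malformed or internally inconsistent."""


class DomainError(VariceaError):
    """An argument is outside the domain an operation is defined on.

    Deliberately not a ValueError: it must survive pydantic validation
    contexts unwrapped.
    """
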