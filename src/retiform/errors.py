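"""Exception hierarchy shared across the package."""


class RetiformError(Exception):
    """Base class for all package errors."""


class ValidationError(RetiformError):
    """A value violates a structural contract (malformed permutation, loop, table)."""


class BoundError(ValidationError):
    """A numeric argument is outside its permitted range."""


class OperatorError(ValidationError):
    """A negation-operator index is outside 1..n-1."""


class RefusalError(RetiformError):
    """The requested computation is deliberately refused (e.g. enumeration at n >= 5)."""


class ConfigurationError(RetiformError):
    """A configuration file or parameter set is invalid."""


class FormatError(RetiformError):
    """An unknown or unparsable serialization format."""
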