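"""Exception types shared across the package."""


class DSUNetError(Exception):
    """Base class for package errors."""


class InvalidInputError(DSUNetError, ValueError):
    """A value violates an operation's precondition."""


class ShapeError(DSUNetError, ValueError):
    """Tensor dimensions are inconsistent with the operation's contract."""


class NumericError(DSUNetError, ArithmeticError):
    """A computation produced non-finite values."""


class ConfigError(DSUNetError, ValueError):
    """A run configuration is malformed or internally inconsistent."""


class DataError(DSUNetError, IOError):
    """Input data is missing or unreadable."""
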