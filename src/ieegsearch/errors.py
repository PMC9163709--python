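"""Exception hierarchy."""


class IEEGSearchError(Exception):
    """Base class for package errors."""


class ParameterError(IEEGSearchError, ValueError):
    """Invalid parameter value (band edges, durations, enum names, ...)."""


class DataError(IEEGSearchError, ValueError):
    """Input data violates an operation's precondition."""


class FormatError(IEEGSearchError, ValueError):
    """A file does not conform to the expected schema.

    ``field`` names the offending field when known.
    """

    def __init__(self, message: str, field: str | None = None):
        super().__init__(message)
        self.field = field


class ContractError(IEEGSearchError, ValueError):
    """Feature maps or vectors do not honour the declared backend contract."""
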