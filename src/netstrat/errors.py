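"""Exception hierarchy shared across the pipeline stages."""


class NetstratError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NetstratError):
    """A configuration value is inconsistent or out of range."""


class FormatError(NetstratError):
    """An input file does not conform to the expected layout."""


class DataError(NetstratError):
    """Input data violate a contract (negative scores, empty graph, ...)."""


class ConvergenceError(NetstratError):
    """An iterative solver exhausted its iteration budget."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual
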