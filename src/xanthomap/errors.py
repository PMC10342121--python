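"""Exception hierarchy shared by all pipeline stages.

The CLI maps these onto exit codes: configuration problems exit 2, data
problems exit 3, numerical failures exit 4.
"""


class XanthomapError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(XanthomapError):
    """Invalid configuration value (bad band parameter, unknown config key...)."""

    exit_code = 2


class DataError(XanthomapError):
    """Invalid or inconsistent input data (domain errors, parse errors...)."""

    exit_code = 3


class NumericalError(XanthomapError):
    """A numerical procedure failed to converge or produced a degenerate result."""

    exit_code = 4

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
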