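"""Exception hierarchy shared across the package.

``DataError`` marks problems in user-supplied summary statistics (CLI exit
code 1); ``ConfigError`` marks malformed configuration or impossible
parameter combinations (exit code 2).
"""


class TelomrError(Exception):
    """Base class for all package errors."""


class DataError(TelomrError):
    """Invalid or irreconcilable input data."""


class ConfigError(TelomrError):
    """Invalid configuration: missing columns, bad thresholds, bad paths."""


class ConvergenceError(TelomrError):
    """An iterative estimator failed to converge.

    Carries the optimizer diagnostics in ``details``.
    """

    def __init__(self, message: str, details=None):
        super().__init__(message)
        self.details = details
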