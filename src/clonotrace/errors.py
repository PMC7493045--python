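"""Exception types shared across the pipeline.

``ValidationError`` signals bad configuration or malformed parameters
(CLI exit code 2); ``DataError`` signals inconsistent or unusable input
data (CLI exit code 3).
"""


class ClonotraceError(Exception):
    """Base class for all package errors."""


class ValidationError(ClonotraceError):
    """Invalid configuration, parameters, or schema."""

    exit_code = 2


class DataError(ClonotraceError):
    """Inconsistent or unusable input data."""

    exit_code = 3
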