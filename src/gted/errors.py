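"""Exception hierarchy.

ConfigError covers bad parameters/files-of-parameters (CLI exit code 2),
DataError covers malformed or inconsistent sequence data (exit code 3).
"""


class GtedError(Exception):
    """Base class for all package errors."""


class ConfigError(GtedError):
    """Invalid configuration or parameter value."""


class DataError(GtedError):
    """Invalid or inconsistent input data."""
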