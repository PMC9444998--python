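"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3,
anything else -> 4.
"""


class CogClockError(Exception):
    """Base class for all package errors."""


class ConfigError(CogClockError, ValueError):
    """Invalid configuration; the message names the offending field."""


class DataError(CogClockError, ValueError):
    """Malformed or inconsistent input data."""
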