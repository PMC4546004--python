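"""Exception hierarchy.

Config/usage problems raise :class:`ConfigError`; problems with the data
themselves (malformed sequences, impossible tables) raise :class:`DataError`.
The CLI maps these onto distinct exit codes.
"""


class UrocyonError(Exception):
    """Base class for all package errors."""


class ConfigError(UrocyonError):
    """Invalid configuration or parameters."""


class DataError(UrocyonError):
    """Malformed or inconsistent input data."""


class MalformedSequenceError(DataError):
    """A sequence violates a length or alphabet precondition."""


class UndefinedResultError(DataError):
    """The requested statistic is undefined for this input (e.g. n < 2)."""
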