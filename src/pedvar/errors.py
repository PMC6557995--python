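"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: 2 configuration, 3 data inconsistency,
4 parse failure.
"""


class PedvarError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(PedvarError):
    """Invalid configuration value; message names the offending field."""

    exit_code = 2


class DataError(PedvarError):
    """Inconsistent input data (e.g. negative cohort subtraction)."""

    exit_code = 3


class ParseError(PedvarError):
    """Malformed input file; message carries the line number when known."""

    exit_code = 4
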