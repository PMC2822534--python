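"""Exception hierarchy shared across the pipeline.

Configuration problems (bad parameters, missing samples, duplicate ids) and
data problems (malformed files, degenerate inputs) are kept distinct so the
command line can map them to different exit codes.
"""


class MirsieveError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MirsieveError):
    """Invalid parameters, unknown identifiers, inconsistent settings."""

    exit_code = 2


class DataError(MirsieveError):
    """Input data that cannot be processed (malformed or degenerate)."""

    exit_code = 3


class ParseError(DataError):
    """A record or row in an input file failed to parse.

    Carries the offending location (line or row number) in the message.
    """
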