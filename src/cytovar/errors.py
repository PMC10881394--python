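"""Exception hierarchy.

Exit-code mapping used by the CLI: configuration errors exit 2, data errors
exit 3, numerical failures exit 4.
"""


class CytovarError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(CytovarError):
    """Invalid configuration; the message names the offending field."""

    exit_code = 2


class DataError(CytovarError):
    """Input data violates a schema or content contract."""

    exit_code = 3


class InsufficientDataError(DataError):
    """Too few observations (or too little variation) to fit a model."""


class NumericalError(CytovarError):
    """A numerical procedure failed."""

    exit_code = 4


class CollinearityError(NumericalError):
    """Design matrix is rank deficient; the message names aliased columns."""
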