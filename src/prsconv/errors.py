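"""Exception hierarchy shared across the pipeline.

The CLI maps these to exit codes: ConfigurationError -> 2, DataError -> 3,
NumericalError -> 4.
"""


class PrsconvError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PrsconvError):
    """An invalid configuration value; the message names the offending field."""


class DataError(PrsconvError):
    """Input data violate a precondition (missing file, empty panel, ...)."""


class NumericalError(PrsconvError):
    """A numerical routine failed to converge or produced a degenerate result."""
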