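"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: usage/parameter problems -> 2,
data/format problems -> 3, numerical failures -> 4.
"""


class SpikeTypeError(Exception):
    """Base class for all package errors."""


class ParameterError(SpikeTypeError, ValueError):
    """Invalid argument or configuration (CLI exit code 2)."""


class FormatError(SpikeTypeError):
    """Malformed or unreadable input data (CLI exit code 3)."""


class ModelVersionError(FormatError):
    """Model file written by an unsupported schema version."""


class NumericalError(SpikeTypeError):
    """A computation could not produce a valid result (CLI exit code 4)."""
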