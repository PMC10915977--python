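"""Exception hierarchy shared across the toolkit.

The CLI maps these onto exit codes: configuration problems exit 2, data
problems (format, channel mismatch, degenerate signals) exit 3, anything
else exit 4.
"""


class MicrostateError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(MicrostateError):
    """Invalid or missing configuration (bad k, missing sampling rate, ...)."""


class DataError(MicrostateError):
    """Base class for problems with input data."""


class FormatError(DataError):
    """A file could not be parsed; the message names the offending location."""


class ChannelMismatchError(DataError):
    """Requested channels are absent from a recording or template set."""


class UndefinedCorrelationError(DataError):
    """Spatial correlation requested on a constant (flat) topography."""
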