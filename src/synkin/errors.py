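"""Exception hierarchy.

Every error raised by this package derives from :class:`SynkinError`, so
callers (and the CLI) can distinguish pipeline failures from programming
errors. Subclasses mirror the kinds of contract violations the modules
document: malformed input files, invalid parameters, structurally
incompatible inputs, events outside a recording, bad data values, and
statistics that are undefined for the given input.
"""


class SynkinError(Exception):
    """Base class for all errors raised by synkin."""


class FormatError(SynkinError):
    """A delimited-text file is malformed (ragged rows, bad cells, dup headers)."""


class ParameterError(SynkinError, ValueError):
    """A numeric parameter or input size violates a documented precondition."""


class StructuralError(SynkinError):
    """Inputs are individually valid but mutually incompatible (shapes, labels)."""


class EventError(SynkinError):
    """An onset/offset window does not fit the recording it refers to."""


class DataError(SynkinError):
    """Data values violate a domain requirement (negative EMG, silent channel)."""


class UndefinedStatisticError(SynkinError):
    """The requested statistic is undefined for this input (e.g. zero variance)."""


class ConfigError(SynkinError):
    """A configuration file or CLI option set is invalid."""


class PipelineError(SynkinError):
    """A pipeline stage failed; the message names the stage."""
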