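"""Exception hierarchy.

Every error raised by this package derives from :class:`HitFcaError`, so
callers (and the CLI) can distinguish assay-level failures from bugs.
"""


class HitFcaError(Exception):
    """Base class for all errors raised by hitfca."""


class FormatError(HitFcaError):
    """A file could not be parsed under the named dialect."""


class ChannelError(HitFcaError):
    """A required channel is missing or cannot be mapped to its role."""


class StateError(HitFcaError):
    """An operation was applied to data in the wrong scale or state."""


class NumericalError(HitFcaError):
    """A numerical prerequisite failed (e.g. singular spillover matrix)."""


class ParameterError(HitFcaError):
    """A parameter is outside its admissible range."""


class DataError(HitFcaError):
    """The data do not support the requested statistic (too few events...)."""


class CutoffError(HitFcaError):
    """No usable activation cutoff exists; the PRP is not usable."""


class ConsistencyError(HitFcaError):
    """Inputs that must agree (e.g. sample ids across runs) do not."""
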