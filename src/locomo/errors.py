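"""Exception hierarchy.

All package errors derive from :class:`LocomoError` so callers can catch
one base; configuration mistakes and data problems are distinguished
because the command-line layer maps them to different exit codes.
"""


class LocomoError(Exception):
    """Base class for all errors raised by this package."""


class DomainError(LocomoError, ValueError):
    """An input value is outside the domain of an operation."""


class ConfigError(LocomoError, ValueError):
    """A configuration object is inconsistent or out of range."""


class SegmentationError(LocomoError):
    """Transition segmentation failed on a recording."""


class FeatureError(LocomoError):
    """A feature could not be computed (non-finite or undefined)."""
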