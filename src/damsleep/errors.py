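"""Exception hierarchy for the damsleep pipeline.

Every error raised on bad input derives from :class:`DamsleepError` so callers
(and the CLI) can distinguish pipeline failures from programming errors.
"""


class DamsleepError(Exception):
    """Base class for all damsleep errors."""


class DamParseError(DamsleepError):
    """A monitor-file row could not be parsed (names the offending line)."""


class DamOrderingError(DamsleepError):
    """Monitor-file timestamps are not strictly increasing."""


class DamGapError(DamsleepError):
    """Monitor-file timestamps contain a gap; missing spans are never zero-filled."""


class CapacityError(DamsleepError):
    """More channels than a single 32-channel monitor file can carry."""


class ChannelLookupError(DamsleepError):
    """A design row references a monitor/channel that was not recorded."""


class ConfigurationError(DamsleepError):
    """Invalid protocol, preset, reference group or run configuration."""


class CoverageError(DamsleepError):
    """An analysis window is not fully covered by the recording."""


class EmptyInputError(DamsleepError):
    """An operation received an empty trace or an empty set of flies."""


class DegenerateVarianceError(DamsleepError):
    """Zero pooled variance with unequal means: the test statistic is undefined."""


class NormalizationError(DamsleepError):
    """Percent-change normalization against a zero reference mean."""


class InsufficientGroupError(DamsleepError):
    """A tested group has fewer than two flies (names the group)."""
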