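"""Exception hierarchy shared across the pipeline."""


class WavepacError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(WavepacError, ValueError):
    """An argument is outside its documented domain."""


class IntervalError(ParameterError):
    """An artifact interval is malformed (start > end, out of range)."""


class ReferencingError(WavepacError):
    """Too few good channels to build the requested reference."""


class FilteringError(WavepacError):
    """Signal too short for the designed filter."""


class ChannelLookupError(WavepacError, KeyError):
    """A requested channel label is absent or marked bad."""


class UndefinedMetricError(WavepacError):
    """A metric has no defined value (too few cycles, nonpositive mean,
    constant input, zero pooled SD, ...)."""


class InsufficientDataError(WavepacError):
    """Not enough usable samples (e.g. an empty phase bin)."""
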