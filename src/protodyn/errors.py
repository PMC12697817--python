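"""Exception hierarchy shared by all protodyn modules."""


class ProtodynError(Exception):
    """Base class for all protodyn errors."""


class UsageError(ProtodynError, ValueError):
    """Caller violated a precondition (bad argument, too little data)."""


class FormatError(ProtodynError):
    """Input file or waveform does not match the expected layout."""


class DataError(ProtodynError):
    """Input data are structurally valid but semantically broken
    (e.g. non-monotone time axis)."""


class FitError(ProtodynError):
    """A nonlinear fit failed to converge."""


class DegenerateFitWarning(UserWarning):
    """A fit succeeded but the model collapsed (e.g. zero decay rate)."""


class DegenerateRangeWarning(UserWarning):
    """A statistic was computed on data with zero spread."""
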