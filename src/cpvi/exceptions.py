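"""Exception hierarchy shared across the package."""


class CpviError(ValueError):
    """Base class for all cpvi errors."""


class FormatError(CpviError):
    """A file does not conform to the expected format (missing columns/channels)."""


class SamplingError(CpviError):
    """Timestamps are not uniformly sampled within tolerance."""


class UnsupportedRateError(CpviError):
    """Sampling rate cannot be decimated to the analysis rate by an integer factor."""


class InputError(CpviError):
    """Invalid or degenerate input to an operation."""


class SplitError(CpviError):
    """A holdout split cannot be formed (e.g. single-class dataset)."""


class SelectionError(CpviError):
    """Optimal-setting selection failed (e.g. no evaluable grid cell)."""
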