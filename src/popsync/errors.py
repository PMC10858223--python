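"""Exception hierarchy shared by all analysis stages."""


class PopsyncError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(PopsyncError, ValueError):
    """A stage parameter violates its contract (negative rate, bad range...)."""


class InvalidInputError(PopsyncError, ValueError):
    """An input object violates its contract (empty epochs, flat waveform...)."""


class InsufficientDataError(PopsyncError, ValueError):
    """Not enough spikes/units/trials to compute the requested statistic."""


class FormatError(PopsyncError, ValueError):
    """An on-disk file does not conform to the expected dialect."""


class ConfigurationError(PopsyncError, ValueError):
    """A pipeline config requests a stage whose inputs are missing."""
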