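"""Exception types shared across the simulator and metrics modules."""


class ThetaSweepError(Exception):
    """Base class for package-specific errors."""


class NumericalDivergenceError(ThetaSweepError):
    """A state variable became NaN/Inf during integration."""


class UndefinedDirectionError(ThetaSweepError):
    """Population vector too incoherent to define a bump centre."""


class AmbiguityError(ThetaSweepError):
    """Phase trace jumps by half a period or more in one step."""


class InsufficientDataError(ThetaSweepError):
    """Not enough valid records/spikes for the requested statistic."""


class NormalizationError(ThetaSweepError):
    """Autocorrelogram has no usable normalization peak."""


class FitError(ThetaSweepError):
    """Bounded least-squares fit failed at every start point."""


class UndefinedValueError(ThetaSweepError):
    """A statistic is undefined for the given input (e.g. 0/0)."""
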