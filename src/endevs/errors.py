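"""Exception hierarchy for endevs validation failures."""


class EndevsError(Exception):
    """Base class for all endevs errors."""


class ValidationError(EndevsError, ValueError):
    """Invalid input to an endevs operation."""


class DegenerateDistributionError(ValidationError):
    """Probability vector is empty or carries no mass."""


class DegenerateDevianceError(ValidationError):
    """A deviance vector has no positive magnitude, so no deviation pattern exists."""


class ThresholdError(ValidationError):
    """Extreme-value threshold c outside (0, 1]."""


class UnsupportedOrderError(ValidationError):
    """Order q outside the domain of the requested quantity."""


class ZeroVarianceError(ValidationError):
    """Predictive-plus-noise variance is zero for some feature."""
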