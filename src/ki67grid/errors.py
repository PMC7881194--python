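"""Exception hierarchy shared across the pipeline."""


class Ki67GridError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(Ki67GridError):
    """A column map, parameter set, or config file is unusable."""


class ValidationError(Ki67GridError):
    """Input data violate a structural invariant (counts, ranges, duplicates)."""


class EmptySlideError(Ki67GridError):
    """A scoring operation was asked to run with zero valid grids."""


class UndefinedStatisticError(Ki67GridError):
    """A statistic is undefined for the given input (zero cells, zero variance)."""
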