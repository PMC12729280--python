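"""Exception and warning types shared across the package."""


class GrowthKinError(Exception):
    """Base class for all package errors."""


class InvalidInputError(GrowthKinError, ValueError):
    """A scalar input violates its domain (negative OD, dilution < 1, ...)."""


class DomainError(GrowthKinError, ValueError):
    """A model parameter violates the model's domain."""


class DegenerateStitchError(DomainError):
    """Hybrid two-phase parameters place the stitch value at or above K."""


class ParseError(GrowthKinError, ValueError):
    """A CSV input does not match the documented schema."""


class EmptySeriesError(ParseError):
    """The data section of an input file contains no rows."""


class InconsistentLedgerError(GrowthKinError, ValueError):
    """The volume ledger drops to zero or below at a sample time."""


class InsufficientDataError(GrowthKinError, ValueError):
    """Too few observations for the requested operation."""


class DegenerateDataError(GrowthKinError, ValueError):
    """Observations carry no usable signal (e.g. constant biomass)."""


class MissingTemperatureError(GrowthKinError, ValueError):
    """No temperature records inside the requested window."""


class UnidentifiableError(GrowthKinError, ValueError):
    """The design is rank-deficient for one or more parameters."""


class ConfigurationError(GrowthKinError, ValueError):
    """An invalid run configuration (unknown model name, empty model set, ...)."""


class CalibrationRangeWarning(UserWarning):
    """An OD reading lies outside the calibrated linear range."""
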