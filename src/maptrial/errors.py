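"""Exceptions shared across the pipeline."""


class MapTrialError(Exception):
    """Base class for all package errors."""


class InvalidReadingError(MapTrialError, ValueError):
    """A blood-pressure reading violates basic physiologic constraints."""


class InsufficientReadingsError(MapTrialError, ValueError):
    """Fewer than two qualifying pre-illness BP readings are available.

    Corresponds to the screening exclusion for patients whose pre-morbid
    blood pressure cannot be established.
    """


class ContractError(MapTrialError, ValueError):
    """An operation was called outside its documented preconditions."""


class EmptySeriesError(MapTrialError, ValueError):
    """A metric was requested on a series with no usable observations."""


class EmptyWindowError(MapTrialError, ValueError):
    """No vasopressor epochs: the active treatment window is undefined."""


class ConfigError(MapTrialError, ValueError):
    """A simulation or analysis configuration value is invalid."""
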