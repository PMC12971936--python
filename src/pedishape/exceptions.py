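"""Exception and warning types used across the package."""


class PedishapeError(Exception):
    """Base class for package errors."""


class ConfigurationError(PedishapeError, ValueError):
    """Invalid simulation or model configuration."""


class CohortSchemaError(PedishapeError, ValueError):
    """A required column is missing from a cohort file."""


class CohortParseError(PedishapeError, ValueError):
    """A measurement field could not be parsed as a number."""


class MeasurementDomainError(PedishapeError, ValueError):
    """A measurement is outside the physiologic/mathematical domain of an index."""


class ReferenceLookupError(PedishapeError, KeyError):
    """A (sex, age) or (sex, stratum, level) combination is not covered by a reference."""


class StratificationError(PedishapeError, ValueError):
    """A stratification cell is empty where data are required."""


class DegenerateCellError(PedishapeError, ValueError):
    """A standardization cell has zero variance."""


class RankDeficientDesignError(PedishapeError, ValueError):
    """The regression design matrix is rank deficient (e.g. an absent factor level)."""


class UndefinedMetricError(PedishapeError, ValueError):
    """A screening metric is undefined (single-class truth)."""


class PoolingWarning(UserWarning):
    """A sparse standardization cell was pooled with an adjacent age bin."""


class SmallStratumWarning(UserWarning):
    """A reference stratum is below the minimum recommended size."""


class DegenerateQuartileWarning(UserWarning):
    """Tied quartile cutpoints collapse adjacent quartile groups."""


class SeparationWarning(UserWarning):
    """Complete or quasi-complete separation detected in a logistic fit."""
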