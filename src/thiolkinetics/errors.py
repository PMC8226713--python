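"""Exception hierarchy shared across the package."""


class ThiolKineticsError(Exception):
    """Base class for all package-specific errors."""


class DatasetFormatError(ThiolKineticsError):
    """A CSV is structurally wrong (missing columns, empty file)."""


class DatasetParseError(ThiolKineticsError):
    """A CSV row holds unparseable values; carries the offending row numbers."""


class MissingBaselineError(ThiolKineticsError):
    """A (treatment, heat_state, temperature) group lacks a day-0 observation."""


class GroupNotFoundError(ThiolKineticsError):
    """A requested (treatment, heat_state) group is absent from the dataset."""


class GroupingError(ThiolKineticsError):
    """Observations passed to a single-group fit span multiple groups."""


class DegenerateDesignError(ThiolKineticsError):
    """Too few distinct design points to identify the model."""


class TransformDomainError(ThiolKineticsError):
    """Non-positive responses forbid the log/reciprocal order transforms."""


class LogDomainError(ThiolKineticsError):
    """A non-positive rate constant forbids the Arrhenius linearization."""


class IdentifiabilityError(ThiolKineticsError):
    """The data cannot separate the parameters (e.g. one temperature only)."""


class FitFailureError(ThiolKineticsError):
    """Iterative optimisation did not converge; carries the last iterate."""

    def __init__(self, message, last_params=None, residual_norm=None):
        super().__init__(message)
        self.last_params = last_params
        self.residual_norm = residual_norm


class ConfigurationError(ThiolKineticsError):
    """Invalid user configuration (ratios, duplicate models, bad grids)."""


class EncodingError(ThiolKineticsError):
    """A categorical level unseen by the fitted feature encoder."""


class DesignMatrixError(ThiolKineticsError):
    """Rank-deficient or otherwise unusable regression design."""


class LeakageError(ThiolKineticsError):
    """Hold-out data overlaps the conditions used to build the predictor."""


class ZeroVarianceError(ThiolKineticsError):
    """The observed vector is constant, so R^2 is undefined."""
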