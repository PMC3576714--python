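"""Exception hierarchy."""


class LVControlError(Exception):
    """Base class for all package errors."""


class ParameterError(LVControlError, ValueError):
    """Invalid model or basis parameter."""


class DataError(LVControlError, ValueError):
    """Malformed event-train data (unsorted times, missing outputs, ...)."""


class ConfigurationError(LVControlError, ValueError):
    """Incompatible configuration, e.g. model fitted with a different basis."""


class EstimationError(LVControlError, RuntimeError):
    """Least-squares estimation failure."""


class SingularDesignError(EstimationError):
    """Rank-deficient design matrix without regularization."""

    def __init__(self, message, columns=None):
        super().__init__(message)
        self.columns = list(columns) if columns is not None else []


class UnsolvableEventError(LVControlError, RuntimeError):
    """Inverse solve degenerate at one event (a ~ 0 and b ~ 0)."""

    def __init__(self, message, index=None):
        super().__init__(message)
        self.index = index


class UndefinedMetricError(LVControlError, ValueError):
    """Metric denominator is zero (constant observations or all-zero signal)."""
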