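"""Exception hierarchy for shiftrisk.

All package-raised errors derive from :class:`ShiftRiskError` so callers can
catch one base class at pipeline boundaries.
"""


class ShiftRiskError(Exception):
    """Base class for all shiftrisk errors."""


class InvalidParameterError(ShiftRiskError, ValueError):
    """A parameter violates its documented precondition."""


class UnknownScenarioError(ShiftRiskError, KeyError):
    """Requested scenario id does not map to a generator recipe."""


class ShapeError(ShiftRiskError, ValueError):
    """Array dimensions or lengths are inconsistent."""


class DegenerateDataError(ShiftRiskError, ValueError):
    """Data is too degenerate for the requested statistic (e.g. singular
    covariance, all-identical points)."""


class UnlabeledDataError(ShiftRiskError, ValueError):
    """An operation requiring labels received an unlabeled point set."""


class UndefinedAUCError(ShiftRiskError, ValueError):
    """ROC AUC is undefined (single-class test set)."""


class EmptyDomainError(ShiftRiskError, ValueError):
    """A source or target sample is empty."""


class SolverError(ShiftRiskError, RuntimeError):
    """The quadratic-program solver failed to converge."""


class DegenerateGroundTruthError(ShiftRiskError, ValueError):
    """Ground-truth risks are ~0; percentage metrics are undefined."""


class EmptyPoolError(ShiftRiskError, ValueError):
    """No model survived the ROC-AUC filter."""


class CannotSplitError(ShiftRiskError, ValueError):
    """Too few points to split into train and test."""


class InvalidRadiusError(ShiftRiskError, ValueError):
    """A clustering-curve radius exceeds the domain diameter."""


class ExperimentError(ShiftRiskError, RuntimeError):
    """Every trial of an experiment failed."""
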