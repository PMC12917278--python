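"""Risk estimates from error and weight vectors, and accuracy metrics.

The target risk is the expectation of the model's error under the target
density, R = ∫ e(x) p(x) dx. Its Monte-Carlo benchmark (GT) averages
errors over labeled target test points; every estimator below uses only
source-side labels, reweighted (or not) toward the target distribution:

* NW — the unweighted source average (all-ones weights): biased under shift.
* IW / Classifier / KMM — (1/n) sum_i w_i e_i with the corresponding
  weight vector.

Estimator quality over repeated trials is summarized by MAPE, RMSE and RMSPE
between the estimated and ground-truth risks (percentage metrics x100).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .blackbox import ErrorVector
from .exceptions import DegenerateGroundTruthError, InvalidParameterError, ShapeError
from .weights import WeightVector

__all__ = ["RiskEstimate", "ground_truth_risk", "nw_risk", "weighted_risk", "metrics"]

GT_GUARD = 1e-12


@dataclass
class RiskEstimate:
    """A scalar risk estimate tagged with its estimating method."""

    value: float
    method: str
    n_used: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.value) or self.value < 0:
            raise InvalidParameterError("risk estimate must be finite and >= 0")


def ground_truth_risk(target_test_errors: ErrorVector) -> RiskEstimate:
    """Unbiased Monte-Carlo benchmark: mean error over labeled target test points."""
    if len(target_test_errors) == 0:
        raise InvalidParameterError("empty error vector")
    return RiskEstimate(
        value=float(np.mean(target_test_errors.values)),
        method="gt",
        n_used=len(target_test_errors),
    )


def nw_risk(source_test_errors: ErrorVector) -> RiskEstimate:
    """The no-weighting estimator: plain source test average (all-ones weights)."""
    if len(source_test_errors) == 0:
        raise InvalidParameterError("empty error vector")
    return RiskEstimate(
        value=float(np.mean(source_test_errors.values)),
        method="nw",
        n_used=len(source_test_errors),
    )


def weighted_risk(
    source_test_errors: ErrorVector, weights: WeightVector
) -> RiskEstimate:
    """(1/n) sum_i w_i e_i over source test points; method follows the weights."""
    e = source_test_errors.values
    w = weights.values
    if e.shape != w.shape:
        raise ShapeError(f"errors {e.shape} and weights {w.shape} differ in length")
    return RiskEstimate(
        value=float(np.mean(w * e)),
        method=weights.method,
        n_used=len(weights),
        metadata=dict(weights.diagnostics),
    )


def metrics(
    gt: Sequence[float], est: Sequence[float]
) -> tuple[float, float, float]:
    """(MAPE %, RMSE, RMSPE %) between ground-truth and estimated risks.

    MAPE  = 100 * mean |gt - est| / gt
    RMSE  = sqrt(mean (gt - est)^2)          (raw risk scale)
    RMSPE = 100 * sqrt(mean ((gt - est)/gt)^2)

    Percentage metrics are undefined when any ground truth is ~0 (an
    error-free model): a guard raises rather than dividing by zero.
    """
    g = np.asarray(gt, dtype=float).ravel()
    e = np.asarray(est, dtype=float).ravel()
    if g.shape != e.shape or g.size == 0:
        raise ShapeError("gt and est must be equal-length nonempty sequences")
    if np.any(g <= GT_GUARD):
        raise DegenerateGroundTruthError(
            "a ground-truth risk is ~0; percentage metrics are undefined"
        )
    rel = (g - e) / g
    mape = 100.0 * float(np.mean(np.abs(rel)))
    rmse = float(np.sqrt(np.mean((g - e) ** 2)))
    rmspe = 100.0 * float(np.sqrt(np.mean(rel**2)))
    return mape, rmse, rmspe
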