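"""Black-box predictive models and their per-point errors.

The risk-estimation problem treats the model under assessment as fixed: it is
trained once on labeled source data and never sees target labels. This module
fits the model families used in the benchmark (gradient boosting for the
synthetic regression track; gradient boosting, logistic regression, random
forest and MLP classifiers for the classification track) and computes the two
error functions: squared error against a known response surface, and log-loss
against binary labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from sklearn.ensemble import (
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.neural_network import MLPClassifier

from ._rng import stream_seed
from .datagen import PointSet, TrueFunction
from .exceptions import (
    InvalidParameterError,
    ShapeError,
    UndefinedAUCError,
    UnlabeledDataError,
)

__all__ = [
    "FittedModel",
    "ErrorVector",
    "MODEL_KINDS",
    "fit_black_box",
    "squared_error",
    "log_loss_error",
    "roc_auc",
]

MODEL_KINDS = ("gb_regressor", "gb_classifier", "logistic", "random_forest", "mlp")

_CLASSIFIER_KINDS = ("gb_classifier", "logistic", "random_forest", "mlp")


@dataclass
class FittedModel:
    """A trained predictor with its provenance.

    ``predict`` maps an (n, d) coordinate array to real predictions —
    probabilities of the positive class for classifier kinds.
    """

    kind: str
    hyperparams: dict
    predict: Callable[[np.ndarray], np.ndarray]
    seed: int = 0

    @property
    def is_classifier(self) -> bool:
        return self.kind in _CLASSIFIER_KINDS

    def to_manifest(self) -> dict:
        return {"kind": self.kind, "hyperparams": dict(self.hyperparams),
                "seed": self.seed}


@dataclass
class ErrorVector:
    """Nonnegative per-point errors aligned with a PointSet's rows."""

    values: np.ndarray
    error_kind: str = "squared"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("errors must be finite")
        if np.any(self.values < 0):
            raise InvalidParameterError("errors must be nonnegative")

    def __len__(self) -> int:
        return self.values.shape[0]


def _make_estimator(kind: str, hyperparams: dict, seed: int):
    params = dict(hyperparams)
    if kind == "gb_regressor":
        return GradientBoostingRegressor(random_state=seed, **params)
    if kind == "gb_classifier":
        return GradientBoostingClassifier(random_state=seed, **params)
    if kind == "logistic":
        params.setdefault("max_iter", 1000)
        return LogisticRegression(**params)
    if kind == "random_forest":
        return RandomForestClassifier(random_state=seed, **params)
    if kind == "mlp":
        return MLPClassifier(random_state=seed, **params)
    raise InvalidParameterError(f"unknown model kind {kind!r}; known: {MODEL_KINDS}")


def fit_black_box(
    train: PointSet,
    kind: str = "gb_regressor",
    hyperparams: Optional[dict] = None,
    seed: int = 0,
) -> FittedModel:
    """Fit a model on labeled source training data.

    Library-default hyperparameters are used unless overridden (no tuning is
    performed anywhere in the benchmark). Deterministic given ``seed``; target
    labels are never an input.
    """
    if train.labels is None:
        raise UnlabeledDataError("training PointSet has no labels")
    hyperparams = hyperparams or {}
    est = _make_estimator(kind, hyperparams, stream_seed(seed, "model"))
    X, y = train.coords, train.labels
    if kind in _CLASSIFIER_KINDS:
        y = y.astype(int)
        classes = np.unique(y)
        if len(classes) == 1:
            # Degenerate training labels: the only consistent probability is
            # the constant one; fitting would fail in several libraries.
            only = float(classes[0])

            def predict(x: np.ndarray) -> np.ndarray:
                return np.full(np.atleast_2d(x).shape[0], only)

        else:
            est.fit(X, y)
            pos = int(np.argmax(est.classes_))

            def predict(x: np.ndarray) -> np.ndarray:
                return est.predict_proba(np.atleast_2d(x))[:, pos]

    else:
        est.fit(X, y)

        def predict(x: np.ndarray) -> np.ndarray:
            return est.predict(np.atleast_2d(x))

    return FittedModel(kind=kind, hyperparams=hyperparams, predict=predict, seed=seed)


def squared_error(
    model: FittedModel, points: PointSet, true_fn: TrueFunction
) -> ErrorVector:
    """e(x_i) = (f(x_i) - fhat(x_i))^2 against the known response surface."""
    f = true_fn(points.coords)
    fhat = model.predict(points.coords)
    return ErrorVector((f - fhat) ** 2, error_kind="squared")


def log_loss_error(
    labels: np.ndarray, probs: np.ndarray, eps: float = 1e-15
) -> ErrorVector:
    """Per-point binary cross-entropy with probabilities clamped to [eps, 1-eps]."""
    y = np.asarray(labels, dtype=float).ravel()
    p = np.asarray(probs, dtype=float).ravel()
    if y.shape != p.shape:
        raise ShapeError(f"labels {y.shape} and probs {p.shape} differ in length")
    if np.any((y != 0) & (y != 1)):
        raise InvalidParameterError("labels must be binary 0/1")
    p = np.clip(p, eps, 1.0 - eps)
    e = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    return ErrorVector(e, error_kind="log_loss")


def roc_auc(model: FittedModel, test: PointSet) -> float:
    """Rank-based AUC of the model's probabilities on a labeled test set."""
    if test.labels is None:
        raise UnlabeledDataError("test PointSet has no labels")
    y = test.labels.astype(int)
    if len(np.unique(y)) < 2:
        raise UndefinedAUCError("ROC AUC undefined: test set has a single class")
    return float(roc_auc_score(y, model.predict(test.coords)))
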