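"""Trial orchestration: repeated scenario runs, metric aggregation, model selection.

One trial of the benchmark workflow: generate a source/target pair for a
scenario, split both 70/30, fit the black-box model on the source training
partition, compute its per-point errors on both test partitions, estimate
weights per method on the test partitions, and turn everything into risk
estimates. The ground-truth benchmark alone touches target labels; every
estimator sees only source labels and unlabeled target coordinates.

Experiments repeat trials under derived seeds and aggregate MAPE/RMSE/RMSPE
per method. The model-selection experiment stress-tests the estimators on a
pool of randomly configured classifiers: each method picks the K models with
the lowest estimated risk, and is scored by the mean *true* risk of its picks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from ._rng import stream_seed, substream
from .blackbox import (
    fit_black_box,
    log_loss_error,
    roc_auc,
    squared_error,
)
from .datagen import (
    PointSet,
    ScenarioConfig,
    TrueFunction,
    make_scenario,
    make_true_function,
    split,
)
from .exceptions import (
    EmptyPoolError,
    InvalidParameterError,
    ExperimentError,
    ShiftRiskError,
    UndefinedAUCError,
)
from .risk import RiskEstimate, ground_truth_risk, metrics, nw_risk, weighted_risk
from .weights import (
    KernelConfig,
    WeightVector,
    build_kmm_problem,
    classifier_weights,
    fit_domain_classifier,
    iw_weights,
    kde_fit,
    median_sigma,
    scott_bandwidth,
    solve_kmm,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TrialResult",
    "MetricsTable",
    "ModelPoolEntry",
    "ALL_METHODS",
    "compute_weights",
    "run_trial",
    "run_experiment",
    "generate_model_pool",
    "model_selection",
    "binary_labels",
]

ALL_METHODS = ("nw", "iw", "classifier", "kmm")
DEFAULT_B = 1000.0
TRAIN_FRAC = 0.7


@dataclass
class TrialResult:
    """Risk estimates and diagnostics from one repetition of the workflow."""

    scenario_id: str
    d: int
    seed: int
    estimates: dict  # method -> RiskEstimate, plus "gt"
    model_summary: dict = field(default_factory=dict)

    def estimate(self, method: str) -> float:
        return self.estimates[method].value


@dataclass
class MetricsTable:
    """Per-method MAPE/RMSE/RMSPE with dispersion over repetitions."""

    table: pd.DataFrame
    n_reps: int

    def value(self, method: str, metric: str) -> float:
        sel = self.table[
            (self.table.method == method) & (self.table.metric == metric)
        ]
        return float(sel.value.iloc[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def binary_labels(
    points: PointSet, true_fn: TrueFunction, seed: int, gain: float = 4.0
) -> PointSet:
    """Attach Bernoulli labels with P(y=1|x) = sigmoid(gain * f(x)).

    Turns the smooth response surface into a spatially structured binary
    classification task for the classification track.
    """
    p = expit(gain * true_fn(points.coords))
    rng = substream(seed, f"labels-{points.domain_tag}")
    y = (rng.uniform(size=points.n) < p).astype(float)
    return points.with_labels(y)


def compute_weights(
    method: str,
    source_train: PointSet,
    target_train: PointSet,
    source_test: PointSet,
    target_test: PointSet,
    seed: int = 0,
    B: float = DEFAULT_B,
    kde_floor: float = 1e-12,
) -> WeightVector:
    """Weight vector for one estimator route on the standard partitions.

    IW fits KDEs on the training partitions and evaluates at source test
    points; the classifier route trains on the training partitions; KMM
    matches the test partitions with the median-heuristic RBF bandwidth
    computed on the source test set.
    """
    if method == "nw":
        return WeightVector(np.ones(source_test.n), method="nw")
    if method == "iw":
        dens_g = kde_fit(source_train, scott_bandwidth(source_train))
        dens_p = kde_fit(target_train, scott_bandwidth(target_train))
        return iw_weights(dens_p, dens_g, source_test, floor=kde_floor)
    if method == "classifier":
        clf = fit_domain_classifier(source_train, target_train, seed=seed)
        return classifier_weights(clf, source_test, clip_max=B)
    if method == "kmm":
        sigma2 = median_sigma(source_test)
        problem = build_kmm_problem(
            source_test, target_test, KernelConfig(sigma2=sigma2, B=B)
        )
        return solve_kmm(problem)
    raise InvalidParameterError(f"unknown method {method!r}; known: {ALL_METHODS}")


def _strip_labels(points: PointSet) -> PointSet:
    return PointSet(points.coords, None, points.domain_tag, points.split_tag)


def run_trial(
    config: ScenarioConfig,
    methods: Sequence[str] = ALL_METHODS,
    seed: int = 0,
    task: str = "regression",
    model_kind: Optional[str] = None,
    B: float = DEFAULT_B,
) -> TrialResult:
    """Execute one generate -> split -> fit -> weight -> estimate repetition.

    ``task`` selects the error function: squared error against the synthetic
    response surface ("regression", gradient-boosted regressor) or log-loss
    on Bernoulli labels ("classification", gradient-boosted classifier).
    """
    for m in methods:
        if m not in ALL_METHODS:
            raise InvalidParameterError(f"unknown method {m!r}")
    cfg = replace(config, seed=seed)
    source, target = make_scenario(cfg)
    true_fn = make_true_function(cfg.d, stream_seed(seed, "true-function"))

    if task == "regression":
        model_kind = model_kind or "gb_regressor"
        source = source.with_labels(true_fn(source.coords))
        target = target.with_labels(true_fn(target.coords))
    elif task == "classification":
        model_kind = model_kind or "gb_classifier"
        source = binary_labels(source, true_fn, seed)
        target = binary_labels(target, true_fn, seed)
    else:
        raise InvalidParameterError("task must be 'regression' or 'classification'")

    src_train, src_test = split(source, TRAIN_FRAC, stream_seed(seed, "split-source"))
    tgt_train, tgt_test = split(target, TRAIN_FRAC, stream_seed(seed, "split-target"))

    model = fit_black_box(src_train, kind=model_kind, seed=stream_seed(seed, "model"))

    if task == "regression":
        src_errors = squared_error(model, src_test, true_fn)
        tgt_errors = squared_error(model, tgt_test, true_fn)
        model_summary = {"kind": model_kind, "task": task}
    else:
        src_errors = log_loss_error(src_test.labels, model.predict(src_test.coords))
        tgt_errors = log_loss_error(tgt_test.labels, model.predict(tgt_test.coords))
        try:
            auc = roc_auc(model, tgt_test)
        except UndefinedAUCError:
            auc = float("nan")
        model_summary = {"kind": model_kind, "task": task, "roc_auc_target": auc}

    # Estimators receive unlabeled partitions only: no code path from target
    # labels into any weight computation.
    u_src_train, u_tgt_train = _strip_labels(src_train), _strip_labels(tgt_train)
    u_src_test, u_tgt_test = _strip_labels(src_test), _strip_labels(tgt_test)

    estimates: dict[str, RiskEstimate] = {
        "gt": ground_truth_risk(tgt_errors)
    }
    for method in methods:
        if method == "nw":
            estimates["nw"] = nw_risk(src_errors)
        else:
            w = compute_weights(
                method, u_src_train, u_tgt_train, u_src_test, u_tgt_test,
                seed=seed, B=B,
            )
            estimates[method] = weighted_risk(src_errors, w)

    return TrialResult(
        scenario_id=cfg.scenario_id,
        d=cfg.d,
        seed=seed,
        estimates=estimates,
        model_summary=model_summary,
    )


def run_experiment(
    config: ScenarioConfig,
    methods: Sequence[str] = ALL_METHODS,
    n_reps: int = 100,
    master_seed: int = 0,
    task: str = "regression",
    model_kind: Optional[str] = None,
    B: float = DEFAULT_B,
    return_trials: bool = False,
):
    """Repeat trials under derived seeds and aggregate the accuracy metrics.

    Trial failures (e.g. degenerate geometry on an unlucky draw) are logged
    and excluded with a count rather than aborting the experiment; an
    experiment where every trial failed raises.
    """
    if n_reps < 1:
        raise InvalidParameterError("n_reps must be >= 1")
    trials: list[TrialResult] = []
    failures = 0
    for i in range(n_reps):
        trial_seed = stream_seed(master_seed, f"trial:{i}")
        try:
            trials.append(
                run_trial(config, methods, seed=trial_seed, task=task,
                          model_kind=model_kind, B=B)
            )
        except ShiftRiskError as exc:
            failures += 1
            logger.warning(
                "trial %d of %s (seed %d) failed: %s",
                i, config.scenario_id, trial_seed, exc,
            )
    if not trials:
        raise ExperimentError(f"all {n_reps} trials of {config.scenario_id} failed")

    table = _aggregate(trials, methods, config, failures)
    if return_trials:
        return table, trials
    return table


def _aggregate(
    trials: list[TrialResult],
    methods: Sequence[str],
    config: ScenarioConfig,
    failures: int,
) -> MetricsTable:
    gt = np.array([t.estimate("gt") for t in trials])
    rows = []
    n = len(trials)
    for method in methods:
        est = np.array([t.estimate(method) for t in trials])
        mape, rmse, rmspe = metrics(gt, est)
        # Per-repetition deviations whose averages the three metrics are;
        # their SD/SEM quantify dispersion across repetitions.
        ape = 100.0 * np.abs((gt - est) / gt)
        ae = np.abs(gt - est)
        for metric_name, value, per_rep in (
            ("mape", mape, ape),
            ("rmse", rmse, ae),
            ("rmspe", rmspe, ape),
        ):
            sd = float(np.std(per_rep, ddof=1)) if n > 1 else float("nan")
            rows.append(
                {
                    "scenario": config.scenario_id,
                    "d": config.d,
                    "method": method,
                    "metric": metric_name,
                    "value": value,
                    "sd": sd,
                    "sem": sd / np.sqrt(n) if n > 1 else float("nan"),
                    "n_reps": n,
                    "n_failed": failures,
                }
            )
    return MetricsTable(table=pd.DataFrame(rows), n_reps=n)


@dataclass
class ModelPoolEntry:
    """One candidate model with its true and estimated target risks."""

    model_id: int
    kind: str
    hyperparams: dict
    roc_auc_target: float
    true_risk: float
    estimated_risk: dict  # method -> value


DEFAULT_HYPERPARAM_RANGES = {
    "n_estimators": (5, 20),
    "max_depth": (1, 4),
    "learning_rate": (0.01, 0.3),
}


def generate_model_pool(
    source: PointSet,
    target: PointSet,
    n_models: int = 200,
    hyperparam_ranges: Optional[dict] = None,
    auc_threshold: float = 0.7,
    seed: int = 0,
    methods: Sequence[str] = ALL_METHODS,
    B: float = DEFAULT_B,
) -> list[ModelPoolEntry]:
    """Train a diverse pool of classifiers and score each with every estimator.

    Half gradient boosting, half random forest, with hyperparameters sampled
    uniformly from the configured ranges (diversity, not tuning). Models
    failing the ROC-AUC filter on the target test set are dropped; weights
    are model-independent and computed once per pool.
    """
    if source.labels is None or target.labels is None:
        raise InvalidParameterError("source and target must carry binary labels")
    if n_models % 2:
        raise InvalidParameterError("n_models must be even (half per family)")
    ranges = dict(DEFAULT_HYPERPARAM_RANGES)
    if hyperparam_ranges:
        ranges.update(hyperparam_ranges)

    src_train, src_test = split(source, TRAIN_FRAC, stream_seed(seed, "split-source"))
    tgt_train, tgt_test = split(target, TRAIN_FRAC, stream_seed(seed, "split-target"))
    u = _strip_labels
    weight_vectors = {
        m: compute_weights(
            m, u(src_train), u(tgt_train), u(src_test), u(tgt_test), seed=seed, B=B
        )
        for m in methods
    }

    rng = substream(seed, "model-pool")
    pool: list[ModelPoolEntry] = []
    for model_id in range(n_models):
        kind = "gb_classifier" if model_id < n_models // 2 else "random_forest"
        hp = {
            "n_estimators": int(rng.integers(ranges["n_estimators"][0],
                                             ranges["n_estimators"][1] + 1)),
            "max_depth": int(rng.integers(ranges["max_depth"][0],
                                          ranges["max_depth"][1] + 1)),
        }
        if kind == "gb_classifier":
            hp["learning_rate"] = float(rng.uniform(*ranges["learning_rate"]))
        model = fit_black_box(
            src_train, kind=kind, hyperparams=hp,
            seed=stream_seed(seed, f"pool-model:{model_id}"),
        )
        try:
            auc = roc_auc(model, tgt_test)
        except UndefinedAUCError:
            continue
        if not auc > auc_threshold:
            continue
        src_errors = log_loss_error(src_test.labels, model.predict(src_test.coords))
        tgt_errors = log_loss_error(tgt_test.labels, model.predict(tgt_test.coords))
        estimated = {
            m: weighted_risk(src_errors, weight_vectors[m]).value for m in methods
        }
        pool.append(
            ModelPoolEntry(
                model_id=model_id,
                kind=kind,
                hyperparams=hp,
                roc_auc_target=auc,
                true_risk=ground_truth_risk(tgt_errors).value,
                estimated_risk=estimated,
            )
        )
    if not pool:
        raise EmptyPoolError(
            f"no model passed the ROC-AUC > {auc_threshold} filter"
        )
    return pool


def model_selection(pool: Sequence[ModelPoolEntry], method: str, K: int = 5) -> float:
    """Mean true risk of the K models with the lowest estimated risk.

    Ties break by model_id. A perfect estimator returns the mean of the K
    smallest true risks; a misleading one selects models that perform poorly
    on the target.
    """
    if K < 1 or K > len(pool):
        raise InvalidParameterError(f"K={K} must lie in [1, {len(pool)}]")
    ranked = sorted(pool, key=lambda e: (e.estimated_risk[method], e.model_id))
    selected = ranked[:K]
    return float(np.mean([e.true_risk for e in selected]))
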