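"""Importance weights for source test points under covariate shift.

Three routes to the density ratio p(x)/g(x) (target over source):

* **KDE ratio (IW)** — multivariate Gaussian kernel density estimates of both
  densities with Scott's-rule bandwidth matrices, divided pointwise with a
  floor on the denominator (the source density can collapse to ~0 in regions
  the target occupies, the classic weight-explosion pathology).
* **Classifier ratio** — a probabilistic domain classifier trained to
  separate source from target points; Bayes' rule converts its posterior into
  the density ratio, clipped for stability.
* **Kernel mean matching (KMM)** — bounded, sum-constrained weights that
  minimize the squared maximum mean discrepancy between the weighted source
  and the target in the RKHS of an RBF kernel, sidestepping density
  estimation entirely. The resulting box-and-simplex-constrained convex QP is
  solved by an accelerated projected-gradient method with an exact capped-
  simplex projection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.spatial.distance import cdist, pdist
from sklearn.ensemble import GradientBoostingClassifier

from ._rng import stream_seed
from .datagen import PointSet
from .exceptions import (
    DegenerateDataError,
    EmptyDomainError,
    InvalidParameterError,
    ShapeError,
    SolverError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BandwidthMatrix",
    "DensityModel",
    "DomainClassifier",
    "KernelConfig",
    "KMMProblem",
    "WeightVector",
    "scott_bandwidth",
    "kde_fit",
    "kde_eval",
    "iw_weights",
    "fit_domain_classifier",
    "classifier_weights",
    "median_sigma",
    "rbf_gram",
    "build_kmm_problem",
    "solve_kmm",
    "kmm_objective",
    "empirical_mmd2",
    "project_capped_simplex",
]


@dataclass
class BandwidthMatrix:
    """Symmetric positive-definite KDE bandwidth matrix (squared domain units)."""

    H: np.ndarray

    def __post_init__(self) -> None:
        self.H = np.atleast_2d(np.asarray(self.H, dtype=float))
        if self.H.shape[0] != self.H.shape[1]:
            raise ShapeError("bandwidth matrix must be square")
        if not np.allclose(self.H, self.H.T, atol=1e-10):
            raise InvalidParameterError("bandwidth matrix must be symmetric")
        if np.linalg.eigvalsh(self.H).min() <= 0:
            raise DegenerateDataError("bandwidth matrix must be positive definite")

    @property
    def d(self) -> int:
        return self.H.shape[0]


def scott_bandwidth(train: PointSet) -> BandwidthMatrix:
    """Scott's rule: H = sample covariance * n^(-2/(d+4)).

    Data-driven, so the kernel adapts to the scale and sample size of each
    domain's training partition.
    """
    if train.n < 2:
        raise DegenerateDataError("Scott's rule needs at least 2 points")
    cov = np.atleast_2d(np.cov(train.coords, rowvar=False))
    if np.linalg.eigvalsh(cov).min() <= 1e-12:
        raise DegenerateDataError(
            "sample covariance is singular; jitter the data or drop constant axes"
        )
    factor = train.n ** (-2.0 / (train.d + 4.0))
    return BandwidthMatrix(cov * factor)


@dataclass
class DensityModel:
    """Gaussian-kernel density estimate anchored at training points."""

    support_points: PointSet
    H: BandwidthMatrix

    def __post_init__(self) -> None:
        if self.support_points.d != self.H.d:
            raise ShapeError("bandwidth dimension must match the data dimension")
        # Precompute the Cholesky factor of H for whitened distances.
        self._L = cholesky(self.H.H, lower=True)
        self._log_norm = -0.5 * (
            self.support_points.d * np.log(2.0 * np.pi)
            + 2.0 * np.log(np.diag(self._L)).sum()
        )

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return kde_eval(self, x)


def kde_fit(train: PointSet, H: BandwidthMatrix) -> DensityModel:
    """Bind training points to a bandwidth: ghat(x) = (1/n) sum_i K_H(x - x_i)."""
    return DensityModel(train, H)


def kde_eval(model: DensityModel, x: np.ndarray) -> np.ndarray:
    """Evaluate the density estimate at query points (vectorized, >= 0)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != model.support_points.d:
        raise ShapeError(
            f"query dimension {x.shape[1]} != train dimension {model.support_points.d}"
        )
    # Whiten pairwise differences: u = L^-1 (x - x_i); then
    # K_H(x - x_i) = |H|^(-1/2) (2 pi)^(-d/2) exp(-||u||^2 / 2).
    diff = x[:, None, :] - model.support_points.coords[None, :, :]  # (m, n, d)
    m, n, d = diff.shape
    u = solve_triangular(model._L, diff.reshape(-1, d).T, lower=True).T
    q = (u**2).sum(axis=1).reshape(m, n)
    dens = np.exp(model._log_norm - 0.5 * q).mean(axis=1)
    return dens


@dataclass
class WeightVector:
    """Nonnegative weights for source test rows, tagged by estimator route."""

    values: np.ndarray
    method: str
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("weights must be finite")
        if np.any(self.values < -1e-9):
            raise InvalidParameterError("weights must be nonnegative")
        self.values = np.maximum(self.values, 0.0)
        self.diagnostics.setdefault("max_weight", float(self.values.max()))

    def __len__(self) -> int:
        return self.values.shape[0]


def iw_weights(
    dens_p: DensityModel,
    dens_g: DensityModel,
    eval_points: PointSet,
    floor: float = 1e-12,
) -> WeightVector:
    """KDE density-ratio weights w_i = phat(x_i) / max(ghat(x_i), floor).

    The floor absorbs vanishing source-density denominators so the estimator
    reproduces the weight-explosion pathology as very large — but finite —
    weights; the number of floored denominators is logged and recorded.
    """
    p = kde_eval(dens_p, eval_points.coords)
    g = kde_eval(dens_g, eval_points.coords)
    floored = int((g < floor).sum())
    if floored:
        logger.warning("iw_weights: %d denominators below floor %.1e", floored, floor)
    w = p / np.maximum(g, floor)
    return WeightVector(w, method="iw", diagnostics={"floored_count": floored})


@dataclass
class DomainClassifier:
    """Probabilistic source-vs-target discriminator with its empirical priors."""

    posterior: object  # callable x -> P(target | x)
    prior_g: float
    prior_p: float
    n_g_train: int
    n_p_train: int

    def prob_target(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(self.posterior(np.atleast_2d(x)), dtype=float)

    def prob_source(self, x: np.ndarray) -> np.ndarray:
        return 1.0 - self.prob_target(x)


def fit_domain_classifier(
    source_train: PointSet, target_train: PointSet, seed: int = 0
) -> DomainClassifier:
    """Train a gradient-boosted classifier on pooled data labeled 0=source, 1=target."""
    if source_train.n == 0 or target_train.n == 0:
        raise EmptyDomainError("both domains must be nonempty")
    if source_train.d != target_train.d:
        raise ShapeError("source and target must share dimensionality")
    X = np.vstack([source_train.coords, target_train.coords])
    y = np.concatenate(
        [np.zeros(source_train.n, dtype=int), np.ones(target_train.n, dtype=int)]
    )
    clf = GradientBoostingClassifier(random_state=stream_seed(seed, "domain-clf"))
    clf.fit(X, y)
    pos = int(np.argmax(clf.classes_))

    def posterior(x: np.ndarray) -> np.ndarray:
        return clf.predict_proba(x)[:, pos]

    n_g, n_p = source_train.n, target_train.n
    return DomainClassifier(
        posterior=posterior,
        prior_g=n_g / (n_g + n_p),
        prior_p=n_p / (n_g + n_p),
        n_g_train=n_g,
        n_p_train=n_p,
    )


def classifier_weights(
    clf: DomainClassifier, eval_points: PointSet, clip_max: float = 1000.0
) -> WeightVector:
    """Bayes-rule density-ratio weights from the domain classifier.

    w_i = (n_g / n_p) * (1 / P(source | x_i) - 1), clipped to [0, clip_max];
    a zero source-posterior yields the clip value rather than infinity.
    """
    p_src = clf.prob_source(eval_points.coords)
    ratio = np.empty_like(p_src)
    zero = p_src <= 0.0
    if zero.any():
        logger.warning(
            "classifier_weights: %d points with P(source|x)=0 hit clip_max", zero.sum()
        )
    ratio[zero] = np.inf
    ratio[~zero] = 1.0 / p_src[~zero] - 1.0
    w = np.clip((clf.n_g_train / clf.n_p_train) * ratio, 0.0, clip_max)
    return WeightVector(
        w, method="classifier", diagnostics={"clipped_count": int(zero.sum())}
    )


def median_sigma(points: PointSet) -> float:
    """Median-heuristic RBF bandwidth: sigma^2 = median ||x_i - x_j||^2 / ln n.

    Self-pairs (i = j) are excluded — including the diagonal's zeros is a
    degenerate reading of the heuristic. Natural logarithm. If all points
    coincide, falls back to sigma^2 = 1 (documented degenerate geometry).
    """
    if points.n < 2:
        raise DegenerateDataError("median heuristic needs at least 2 points")
    sq = pdist(points.coords, metric="sqeuclidean")
    med = float(np.median(sq))
    if med <= 0.0:
        logger.warning("median_sigma: all points identical; falling back to sigma2=1")
        return 1.0
    return med / np.log(points.n)


def rbf_gram(X: PointSet, Z: PointSet, sigma2: float) -> np.ndarray:
    """RBF kernel matrix K_ij = exp(-||x_i - z_j||^2 / (2 sigma^2))."""
    if sigma2 <= 0:
        raise InvalidParameterError("sigma2 must be positive")
    if X.d != Z.d:
        raise ShapeError("point sets must share dimensionality")
    sq = cdist(X.coords, Z.coords, metric="sqeuclidean")
    return np.exp(-sq / (2.0 * sigma2))


@dataclass(frozen=True)
class KernelConfig:
    """RBF bandwidth and the weight bound B of the matching program."""

    sigma2: float
    B: float = 1000.0

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise InvalidParameterError("sigma2 must be positive")
        if self.B < 1:
            raise InvalidParameterError("B must be >= 1 (all-ones must be feasible)")


@dataclass
class KMMProblem:
    """The data of the matching QP: Gram matrix, target-similarity vector, bounds.

    The kernel feature map is never materialized — K and kappa are its only
    footprint. kappa_i is the mean kernel similarity between source test
    point i and all target test points.
    """

    K: np.ndarray
    kappa: np.ndarray
    n_source: int
    n_target: int
    config: KernelConfig


def build_kmm_problem(
    source_test: PointSet, target_test: PointSet, config: KernelConfig
) -> KMMProblem:
    """Assemble K (source-source Gram) and kappa (mean target similarity)."""
    if source_test.n == 0 or target_test.n == 0:
        raise EmptyDomainError("both test sets must be nonempty")
    K = rbf_gram(source_test, source_test, config.sigma2)
    kappa = rbf_gram(source_test, target_test, config.sigma2).mean(axis=1)
    return KMMProblem(
        K=K,
        kappa=kappa,
        n_source=source_test.n,
        n_target=target_test.n,
        config=config,
    )


def kmm_objective(problem: KMMProblem, w: np.ndarray) -> float:
    """The matching objective without its constant term.

    Expanding || mu_target - (1/n_g) sum_j w_j phi(x_j) ||^2 gives
    (1/n_g^2) w'Kw - (2/n_g) kappa'w + const.
    """
    w = np.asarray(w, dtype=float).ravel()
    n_g = problem.n_source
    return float(w @ problem.K @ w / n_g**2 - 2.0 * (problem.kappa @ w) / n_g)


def project_capped_simplex(v: np.ndarray, total: float, cap: float) -> np.ndarray:
    """Euclidean projection onto {w : sum w = total, 0 <= w <= cap}.

    The projection is w_i = clip(v_i - tau, 0, cap) where tau solves the
    monotone piecewise-linear equation sum_i clip(v_i - tau, 0, cap) = total;
    tau is located exactly by sorting the 2n breakpoints (v_i and v_i - cap)
    and interpolating within the crossing segment.
    """
    v = np.asarray(v, dtype=float).ravel()
    n = v.shape[0]
    if cap * n < total - 1e-9:
        raise InvalidParameterError("capped simplex is empty: n * cap < total")
    vs = np.sort(v)
    bp = np.sort(np.concatenate([v - cap, v]))
    prefix = np.concatenate([[0.0], np.cumsum(vs)])
    # f(tau) = cap * #{v_i > tau + cap} + sum over free coords of (v_i - tau)
    i1 = np.searchsorted(vs, bp, side="right")
    i2 = np.searchsorted(vs, bp + cap, side="right")
    f = cap * (n - i2) + (prefix[i2] - prefix[i1]) - (i2 - i1) * bp
    # f is non-increasing in tau; locate the segment where it crosses `total`.
    k = int(np.searchsorted(-f, -total, side="right")) - 1
    k = min(max(k, 0), 2 * n - 1)
    if k == 2 * n - 1:
        tau = float(bp[k])
    else:
        # Counts are constant on the open segment; evaluate them at its
        # midpoint to dodge floating-point ties at the breakpoints.
        mid = 0.5 * (bp[k] + bp[k + 1])
        m1 = int(np.searchsorted(vs, mid, side="right"))
        m2 = int(np.searchsorted(vs, mid + cap, side="right"))
        if m2 > m1:
            tau = (cap * (n - m2) + prefix[m2] - prefix[m1] - total) / (m2 - m1)
        else:
            tau = float(bp[k])
    w = np.clip(v - tau, 0.0, cap)
    if abs(w.sum() - total) > 1e-9 * max(1.0, total):
        # Degenerate tie pattern: fall back to plain bisection.
        lo, hi = float(v.min()) - cap, float(v.max())
        for _ in range(200):
            tau = 0.5 * (lo + hi)
            if np.clip(v - tau, 0.0, cap).sum() > total:
                lo = tau
            else:
                hi = tau
        w = np.clip(v - 0.5 * (lo + hi), 0.0, cap)
    # Polish the simplex constraint on the strictly interior coordinates.
    free = (w > 0.0) & (w < cap)
    gap = total - w.sum()
    if free.any():
        w[free] += gap / free.sum()
        np.clip(w, 0.0, cap, out=w)
    return w


def solve_kmm(
    problem: KMMProblem,
    tol: float = 1e-8,
    max_iter: int = 4_000,
) -> WeightVector:
    """Solve the matching QP by accelerated projected gradient (FISTA).

    minimize (1/n_g^2) w'Kw - (2/n_g) kappa'w
    s.t.     0 <= w_j <= B,  sum_j w_j = n_g

    The all-ones vector is always feasible (B >= 1), so the solution's
    objective never exceeds the unweighted one. Momentum is restarted
    whenever the objective increases; convergence is declared when the
    projected-gradient fixed-point residual drops below ``tol``.
    """
    K = problem.K
    kappa = problem.kappa
    n_g = problem.n_source
    B = problem.config.B

    # Lipschitz constant of the gradient: 2 * lambda_max(K) / n_g^2.
    if n_g <= 400:
        lam_max = float(np.linalg.eigvalsh(K)[-1])
    else:  # power iteration is cheaper for large Gram matrices
        v = np.ones(n_g) / np.sqrt(n_g)
        for _ in range(100):
            v_new = K @ v
            nrm = np.linalg.norm(v_new)
            if nrm == 0:
                break
            v = v_new / nrm
        lam_max = float(v @ K @ v)
    L = max(2.0 * lam_max / n_g**2, 1e-30)

    def grad(w: np.ndarray) -> np.ndarray:
        return 2.0 * (K @ w) / n_g**2 - 2.0 * kappa / n_g

    def fixed_point_residual(w: np.ndarray) -> float:
        return float(
            np.abs(w - project_capped_simplex(w - grad(w) / L, float(n_g), B)).max()
        )

    total = float(n_g)
    w = project_capped_simplex(np.ones(n_g), total, B)
    y = w.copy()
    t = 1.0
    status = "max_iter"
    it = 0
    # Track the best objective seen so the returned point never regresses
    # behind the feasible all-ones start (acceleration is not monotone).
    best_obj = kmm_objective(problem, w)
    w_best = w.copy()
    for it in range(max_iter):
        w_new = project_capped_simplex(y - grad(y) / L, total, B)
        # Gradient-scheme adaptive restart: drop momentum when it points
        # against the progress direction.
        if np.dot(y - w_new, w_new - w) > 0.0:
            t = 1.0
            y = w_new.copy()
        else:
            t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
            y = w_new + ((t - 1.0) / t_new) * (w_new - w)
            t = t_new
        w = w_new
        if it % 10 == 0:
            obj = kmm_objective(problem, w)
            if obj < best_obj:
                best_obj, w_best = obj, w.copy()
            if fixed_point_residual(w) < tol:
                status = "optimal"
                break
    if kmm_objective(problem, w) > best_obj:
        w = w_best
    # One final exact projection guards the constraints to solver precision.
    w = project_capped_simplex(w, total, B)
    if status == "max_iter":
        fp = fixed_point_residual(w)
        if fp > 1e-4:
            raise SolverError(
                f"projected gradient did not converge: fixed-point residual {fp:.2e}"
            )
        logger.warning("solve_kmm: loose convergence (residual %.2e)", fp)
    return WeightVector(
        w,
        method="kmm",
        diagnostics={
            "solver_status": status,
            "iterations": it + 1,
            "objective": kmm_objective(problem, w),
        },
    )


def empirical_mmd2(
    source: PointSet,
    target: PointSet,
    sigma2: float,
    weights: Optional[np.ndarray] = None,
) -> float:
    """Squared empirical maximum mean discrepancy between (weighted) source and target.

    With all-ones weights this is the plain two-sample MMD^2 (biased V-statistic
    form); KMM minimizes exactly this quantity over the feasible weights.
    """
    n_g, n_p = source.n, target.n
    w = np.ones(n_g) if weights is None else np.asarray(weights, dtype=float).ravel()
    if w.shape[0] != n_g:
        raise ShapeError("weights must align with source rows")
    K_ss = rbf_gram(source, source, sigma2)
    K_st = rbf_gram(source, target, sigma2)
    K_tt = rbf_gram(target, target, sigma2)
    return float(
        w @ K_ss @ w / n_g**2
        - 2.0 * (w @ K_st.sum(axis=1)) / (n_g * n_p)
        + K_tt.sum() / n_p**2
    )
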