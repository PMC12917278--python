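"""Synthetic spatial data with controllable covariate shift.

Source/target point clouds live in the box ``[0, 100]^d`` (d = 2..4 in the
benchmark configurations, any d >= 1 is supported). Clustered clouds are drawn
from Gaussian mixtures with randomly placed components whose spread is capped
by a maximum-covariance parameter ``sigma_max`` (the largest eigenvalue of any
component covariance): small values give tight, distinct clusters, large
values (or a uniform sampler) give diffuse clouds. Ten named bidirectional
shift scenarios combine these ingredients into the structural biases seen in
ecological and biomedical surveys: domain truncation, mode expansion and
contraction, correlation (covariance-rotation) shifts, variance scaling and
support mismatch.

The smooth ground-truth response used by the regression benchmark is a
mixture of isotropic Gaussian bumps, giving the fitted model a spatially
varying error surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd

from ._rng import substream
from .exceptions import (
    CannotSplitError,
    InvalidParameterError,
    ShapeError,
    UnknownScenarioError,
)

__all__ = [
    "PointSet",
    "ScenarioConfig",
    "TrueFunction",
    "SCENARIO_IDS",
    "sample_gmm",
    "sample_uniform",
    "make_scenario",
    "make_true_function",
    "split",
    "write_points_csv",
    "read_points_csv",
]

DEFAULT_BOUNDS = (0.0, 100.0)

BoundsLike = Union[tuple, list, np.ndarray]


def _normalize_bounds(bounds: BoundsLike, d: int) -> np.ndarray:
    """Return per-axis bounds as a (d, 2) array."""
    arr = np.asarray(bounds, dtype=float)
    if arr.shape == (2,):
        arr = np.tile(arr, (d, 1))
    if arr.shape != (d, 2):
        raise InvalidParameterError(
            f"bounds must be (low, high) or shape ({d}, 2); got {arr.shape}"
        )
    if not np.all(arr[:, 0] < arr[:, 1]):
        raise InvalidParameterError("each axis must satisfy low < high")
    return arr


@dataclass
class PointSet:
    """An n x d coordinate matrix with optional labels and provenance tags."""

    coords: np.ndarray
    labels: Optional[np.ndarray] = None
    domain_tag: str = "source"
    split_tag: str = "all"

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.ndim != 2 or self.coords.shape[0] < 1:
            raise ShapeError("coords must be a nonempty n x d matrix")
        if not np.all(np.isfinite(self.coords)):
            raise InvalidParameterError("coordinates must be finite")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=float).ravel()
            if self.labels.shape[0] != self.coords.shape[0]:
                raise ShapeError("labels must have one entry per point")
        if self.domain_tag not in ("source", "target"):
            raise InvalidParameterError("domain_tag must be 'source' or 'target'")
        if self.split_tag not in ("train", "test", "all"):
            raise InvalidParameterError("split_tag must be 'train', 'test' or 'all'")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def d(self) -> int:
        return self.coords.shape[1]

    def with_labels(self, labels: np.ndarray) -> "PointSet":
        return PointSet(self.coords, labels, self.domain_tag, self.split_tag)

    def subset(self, idx: np.ndarray, split_tag: Optional[str] = None) -> "PointSet":
        labels = None if self.labels is None else self.labels[idx]
        return PointSet(
            self.coords[idx], labels, self.domain_tag, split_tag or self.split_tag
        )


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterization of one bidirectional shift scenario.

    ``sigma_max_source``/``sigma_max_target`` override the recipe defaults
    when set; the string ``"uniform"`` replaces the GMM with a uniform cloud.
    """

    scenario_id: str
    d: int = 2
    n_points: int = 10_000
    n_components: int = 30
    sigma_max_source: Optional[Union[float, str]] = None
    sigma_max_target: Optional[Union[float, str]] = None
    bounds: BoundsLike = DEFAULT_BOUNDS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 10:
            raise InvalidParameterError("n_points must be >= 10")
        if self.d < 1:
            raise InvalidParameterError("d must be >= 1")
        for name in ("sigma_max_source", "sigma_max_target"):
            v = getattr(self, name)
            if v is not None and v != "uniform" and float(v) <= 0:
                raise InvalidParameterError(f"{name} must be positive or 'uniform'")


@dataclass(frozen=True)
class TrueFunction:
    """Smooth response f(x) = sum_k a_k exp(-||x - c_k||^2 / (2 s_k^2))."""

    centers: np.ndarray
    amplitudes: np.ndarray
    widths: np.ndarray
    seed: int = 0

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        # (n, m) squared distances to bump centers
        d2 = ((x[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        return (self.amplitudes * np.exp(-d2 / (2.0 * self.widths**2))).sum(axis=1)


def make_true_function(
    d: int,
    seed: int,
    n_bumps: int = 10,
    amplitude_range: tuple = (-1.0, 1.0),
    width_range: tuple = (5.0, 25.0),
    bounds: BoundsLike = DEFAULT_BOUNDS,
) -> TrueFunction:
    """Draw a random mixture-of-Gaussian-bumps response surface.

    Defaults (10 bumps, amplitudes U(-1, 1), widths U(5, 25) domain units,
    centers uniform in the box) give multiscale structure so that a fitted
    regressor has spatially varying error.
    """
    if d < 1:
        raise InvalidParameterError("d must be >= 1")
    b = _normalize_bounds(bounds, d)
    rng = substream(seed, "true-function")
    centers = rng.uniform(b[:, 0], b[:, 1], size=(n_bumps, d))
    amplitudes = rng.uniform(*amplitude_range, size=n_bumps)
    widths = rng.uniform(*width_range, size=n_bumps)
    return TrueFunction(centers, amplitudes, widths, seed=seed)


def _random_orthogonal(d: int, rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random rotation via QR of a Gaussian matrix (sign-fixed)."""
    q, r = np.linalg.qr(rng.standard_normal((d, d)))
    return q * np.sign(np.diag(r))


def _component_covariances(
    d: int,
    n_components: int,
    sigma_max: float,
    rng: np.random.Generator,
    diagonal: bool = False,
    eigenvalues: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Sample SPD covariances with largest eigenvalue <= sigma_max.

    Eigenvalues are drawn i.i.d. U(0.2 * sigma_max, sigma_max) (avoiding
    degenerate flat components) and rotated by a random orthogonal matrix,
    unless ``diagonal`` pins the covariance to its eigenvalue diagonal.
    """
    covs = np.empty((n_components, d, d))
    for k in range(n_components):
        if eigenvalues is None:
            lam = rng.uniform(0.2 * sigma_max, sigma_max, size=d)
        else:
            lam = np.asarray(eigenvalues[k], dtype=float)
        if diagonal:
            covs[k] = np.diag(lam)
        else:
            rot = _random_orthogonal(d, rng)
            covs[k] = rot @ np.diag(lam) @ rot.T
    return covs


def sample_gmm(
    d: int,
    n: int,
    sigma_max: float,
    n_components: int = 30,
    bounds: BoundsLike = DEFAULT_BOUNDS,
    seed: int = 0,
    *,
    centers: Optional[np.ndarray] = None,
    diagonal: bool = False,
    eigenvalues: Optional[np.ndarray] = None,
    domain_tag: str = "source",
) -> PointSet:
    """Sample ``n`` points from a random Gaussian mixture inside ``bounds``.

    Component centers are uniform in the (possibly cropped) box, mixture
    weights are uniform, and points falling outside the box are rejected and
    re-sampled so that every returned point lies inside. Fully deterministic
    given ``seed``.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    if sigma_max <= 0:
        raise InvalidParameterError("sigma_max must be positive")
    if n_components < 1:
        raise InvalidParameterError("n_components must be >= 1")
    b = _normalize_bounds(bounds, d)

    rng_centers = substream(seed, "centers")
    rng_covs = substream(seed, "covariances")
    rng_points = substream(seed, "points")

    if centers is None:
        centers = rng_centers.uniform(b[:, 0], b[:, 1], size=(n_components, d))
    else:
        centers = np.atleast_2d(np.asarray(centers, dtype=float))
        n_components = centers.shape[0]
    covs = _component_covariances(
        d, n_components, sigma_max, rng_covs, diagonal=diagonal, eigenvalues=eigenvalues
    )
    chols = np.linalg.cholesky(covs)

    out = np.empty((n, d))
    filled = 0
    max_rounds = 1000
    for _ in range(max_rounds):
        need = n - filled
        if need == 0:
            break
        comp = rng_points.integers(0, n_components, size=need)
        z = rng_points.standard_normal((need, d))
        pts = centers[comp] + np.einsum("kij,kj->ki", chols[comp], z)
        ok = np.all((pts >= b[:, 0]) & (pts <= b[:, 1]), axis=1)
        n_ok = int(ok.sum())
        out[filled : filled + n_ok] = pts[ok]
        filled += n_ok
    else:
        raise InvalidParameterError(
            "rejection sampling failed: components have negligible mass in bounds"
        )
    return PointSet(out, domain_tag=domain_tag)


def sample_uniform(
    d: int,
    n: int,
    bounds: BoundsLike = DEFAULT_BOUNDS,
    seed: int = 0,
    domain_tag: str = "source",
) -> PointSet:
    """i.i.d. uniform points in the box (complete spatial randomness)."""
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    b = _normalize_bounds(bounds, d)
    rng = substream(seed, "points")
    return PointSet(
        rng.uniform(b[:, 0], b[:, 1], size=(n, d)), domain_tag=domain_tag
    )


def _cropped_bounds(b: np.ndarray, axis: int = 1, frac: float = 0.5) -> np.ndarray:
    """Restrict one axis to its lower fraction (default: x2 < midpoint)."""
    out = b.copy()
    lo, hi = out[axis]
    out[axis, 1] = lo + frac * (hi - lo)
    return out


def _center_point(b: np.ndarray) -> np.ndarray:
    return b.mean(axis=1)[None, :]


def _resolve_sigma(override, default):
    return default if override is None else override


def _gmm_or_uniform(cfg, sigma, seed, bounds, n_components, domain_tag, **kw):
    if sigma == "uniform":
        return sample_uniform(cfg.d, cfg.n_points, bounds, seed, domain_tag=domain_tag)
    return sample_gmm(
        cfg.d,
        cfg.n_points,
        float(sigma),
        n_components,
        bounds,
        seed,
        domain_tag=domain_tag,
        **kw,
    )


def _recipe_domain_truncation(cfg, b, seed_s, seed_t, cropped_side):
    crop = _cropped_bounds(b)
    if cropped_side == "source":
        src = _gmm_or_uniform(
            cfg, _resolve_sigma(cfg.sigma_max_source, 50.0), seed_s, crop,
            cfg.n_components, "source",
        )
        tgt = _gmm_or_uniform(
            cfg, _resolve_sigma(cfg.sigma_max_target, 400.0), seed_t, b,
            cfg.n_components, "target",
        )
    else:
        src = _gmm_or_uniform(
            cfg, _resolve_sigma(cfg.sigma_max_source, 400.0), seed_s, b,
            cfg.n_components, "source",
        )
        tgt = _gmm_or_uniform(
            cfg, _resolve_sigma(cfg.sigma_max_target, 50.0), seed_t, crop,
            cfg.n_components, "target",
        )
    return src, tgt


def _recipe_mode(cfg, b, seed_s, seed_t, direction):
    center = _center_point(b)
    if direction == "expansion":  # single centered mode -> tight clusters
        src = _gmm_or_uniform(
            cfg, _resolve_sigma(cfg.sigma_max_source, 50.0), seed_s, b, 1,
            "source", centers=center,
        )
        tgt = _gmm_or_uniform(
            cfg, _resolve_sigma(cfg.sigma_max_target, 10.0), seed_t, b,
            cfg.n_components, "target",
        )
    else:  # contraction: scattered clusters -> single centered mode
        src = _gmm_or_uniform(
            cfg, _resolve_sigma(cfg.sigma_max_source, 10.0), seed_s, b,
            cfg.n_components, "source",
        )
        tgt = _gmm_or_uniform(
            cfg, _resolve_sigma(cfg.sigma_max_target, 50.0), seed_t, b, 1,
            "target", centers=center,
        )
    return src, tgt


def _recipe_correlation(cfg, b, seed_s, seed_t, direction):
    # Single centered component; the only difference between the two domains
    # is the rotation of a shared eigenvalue spectrum, isolating the
    # correlation change as the sole shift.
    sigma = 150.0
    center = _center_point(b)
    lam = substream(cfg.seed, "shared-eigenvalues").uniform(
        0.2 * sigma, sigma, size=(1, cfg.d)
    )
    kw = dict(centers=center, eigenvalues=lam)
    diag_first = direction == "shift"  # diagonal source -> rotated target
    src = sample_gmm(
        cfg.d, cfg.n_points, sigma, 1, b, seed_s,
        diagonal=diag_first, domain_tag="source", **kw,
    )
    tgt = sample_gmm(
        cfg.d, cfg.n_points, sigma, 1, b, seed_t,
        diagonal=not diag_first, domain_tag="target", **kw,
    )
    return src, tgt


def _recipe_variance(cfg, b, seed_s, seed_t, direction):
    if direction == "focusing":
        s_sigma, t_sigma = 400.0, 50.0
    else:  # extrapolation
        s_sigma, t_sigma = 50.0, 400.0
    src = _gmm_or_uniform(
        cfg, _resolve_sigma(cfg.sigma_max_source, s_sigma), seed_s, b,
        cfg.n_components, "source",
    )
    tgt = _gmm_or_uniform(
        cfg, _resolve_sigma(cfg.sigma_max_target, t_sigma), seed_t, b,
        cfg.n_components, "target",
    )
    return src, tgt


def _recipe_support(cfg, b, seed_s, seed_t, direction):
    if direction == "uniform_to_gmm":
        s_sigma, t_sigma = "uniform", 50.0
    else:
        s_sigma, t_sigma = 50.0, "uniform"
    src = _gmm_or_uniform(
        cfg, _resolve_sigma(cfg.sigma_max_source, s_sigma), seed_s, b,
        cfg.n_components, "source",
    )
    tgt = _gmm_or_uniform(
        cfg, _resolve_sigma(cfg.sigma_max_target, t_sigma), seed_t, b,
        cfg.n_components, "target",
    )
    return src, tgt


_RECIPES: dict[str, Callable] = {
    "domain_truncation_cropped_to_full": lambda c, b, s, t: _recipe_domain_truncation(
        c, b, s, t, "source"
    ),
    "domain_truncation_full_to_cropped": lambda c, b, s, t: _recipe_domain_truncation(
        c, b, s, t, "target"
    ),
    "mode_expansion": lambda c, b, s, t: _recipe_mode(c, b, s, t, "expansion"),
    "mode_contraction": lambda c, b, s, t: _recipe_mode(c, b, s, t, "contraction"),
    "correlation_shift": lambda c, b, s, t: _recipe_correlation(c, b, s, t, "shift"),
    "correlation_restoration": lambda c, b, s, t: _recipe_correlation(
        c, b, s, t, "restoration"
    ),
    "variance_focusing": lambda c, b, s, t: _recipe_variance(c, b, s, t, "focusing"),
    "variance_extrapolation": lambda c, b, s, t: _recipe_variance(
        c, b, s, t, "extrapolation"
    ),
    "support_mismatch_uniform_to_gmm": lambda c, b, s, t: _recipe_support(
        c, b, s, t, "uniform_to_gmm"
    ),
    "support_mismatch_gmm_to_uniform": lambda c, b, s, t: _recipe_support(
        c, b, s, t, "gmm_to_uniform"
    ),
}

SCENARIO_IDS = tuple(_RECIPES)


def make_scenario(config: ScenarioConfig) -> tuple[PointSet, PointSet]:
    """Generate the (source, target) pair for a named shift scenario."""
    if config.scenario_id not in _RECIPES:
        raise UnknownScenarioError(
            f"unknown scenario {config.scenario_id!r}; known: {sorted(_RECIPES)}"
        )
    b = _normalize_bounds(config.bounds, config.d)
    seed_s = _derive(config.seed, "scenario-source")
    seed_t = _derive(config.seed, "scenario-target")
    return _RECIPES[config.scenario_id](config, b, seed_s, seed_t)


def _derive(seed: int, name: str) -> int:
    from ._rng import stream_seed

    return stream_seed(seed, name)


def split(
    points: PointSet, train_frac: float = 0.7, seed: int = 0
) -> tuple[PointSet, PointSet]:
    """Random disjoint train/test partition with floor(train_frac * n) train rows."""
    if not 0.0 < train_frac < 1.0:
        raise InvalidParameterError("train_frac must lie in (0, 1)")
    if points.n < 2:
        raise CannotSplitError("need at least 2 points to split")
    rng = substream(seed, "split")
    perm = rng.permutation(points.n)
    n_train = int(np.floor(train_frac * points.n))
    if n_train == 0 or n_train == points.n:
        raise CannotSplitError("train_frac leaves one side empty")
    return (
        points.subset(np.sort(perm[:n_train]), split_tag="train"),
        points.subset(np.sort(perm[n_train:]), split_tag="test"),
    )


def write_points_csv(points: PointSet, path) -> None:
    """Write a point set as CSV with header x1..xd[,y][,domain][,split]."""
    cols = {f"x{i+1}": points.coords[:, i] for i in range(points.d)}
    if points.labels is not None:
        cols["y"] = points.labels
    cols["domain"] = points.domain_tag
    cols["split"] = points.split_tag
    pd.DataFrame(cols).to_csv(path, index=False)


def read_points_csv(path) -> PointSet:
    """Read a point set written by :func:`write_points_csv`."""
    df = pd.read_csv(path)
    coord_cols = [c for c in df.columns if c.startswith("x") and c[1:].isdigit()]
    coord_cols.sort(key=lambda c: int(c[1:]))
    if not coord_cols:
        raise ShapeError("no coordinate columns x1..xd found")
    labels = df["y"].to_numpy() if "y" in df.columns else None
    domain_tag = str(df["domain"].iloc[0]) if "domain" in df.columns else "source"
    split_tag = str(df["split"].iloc[0]) if "split" in df.columns else "all"
    return PointSet(
        df[coord_cols].to_numpy(float), labels, domain_tag, split_tag
    )
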