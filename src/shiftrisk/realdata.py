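"""Adapters for external tabular point data (species occurrences, cell layouts).

Ingestion starts from a prepared CSV with numeric feature columns f1..fD, a
binary label y, and optional year/id columns. The pipeline mirrors the
synthetic track: standardize features, optionally project onto leading
principal components (2/3/4 or all), split into source and target domains
(temporally when a year column exists), and validate the assignment with the
clustering diagnostic so that the more-clustered side is the source.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .datagen import PointSet
from .exceptions import DegenerateDataError, InvalidParameterError, ShapeError
from .lcf import rank_by_clustering

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTable",
    "read_feature_csv",
    "standardize",
    "project_pca",
    "temporal_split",
]


@dataclass
class FeatureTable:
    """Rows of (features, binary label, optional year) with no missing values."""

    features: np.ndarray
    labels: np.ndarray
    years: Optional[np.ndarray] = None
    feature_names: list = field(default_factory=list)
    transform: Optional[dict] = None  # retained standardization statistics

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        self.labels = np.asarray(self.labels, dtype=float).ravel()
        if self.features.shape[0] != self.labels.shape[0]:
            raise ShapeError("features and labels must have equal row counts")
        if self.years is not None:
            self.years = np.asarray(self.years, dtype=int).ravel()
            if self.years.shape[0] != self.features.shape[0]:
                raise ShapeError("years must align with rows")
        if not self.feature_names:
            self.feature_names = [f"f{i+1}" for i in range(self.features.shape[1])]

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]

    def to_pointset(self, domain_tag: str = "source") -> PointSet:
        return PointSet(self.features, self.labels, domain_tag=domain_tag)


def read_feature_csv(path) -> FeatureTable:
    """Read f1..fD[,y][,year][,id] CSV, dropping rows with missing fields."""
    df = pd.read_csv(path)
    n_raw = len(df)
    df = df.dropna()
    if len(df) < n_raw:
        logger.warning("dropped %d rows with missing values", n_raw - len(df))
    feat_cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    feat_cols.sort(key=lambda c: int(c[1:]))
    if not feat_cols:
        raise ShapeError("no feature columns f1..fD found")
    if "y" not in df.columns:
        raise ShapeError("label column 'y' is required")
    years = df["year"].to_numpy(int) if "year" in df.columns else None
    return FeatureTable(
        df[feat_cols].to_numpy(float), df["y"].to_numpy(float), years, feat_cols
    )


def standardize(
    table: FeatureTable, stats_from: Optional[FeatureTable] = None
) -> FeatureTable:
    """Center and scale each feature to zero mean, unit variance.

    Statistics come from ``stats_from`` (typically the pooled source+target
    training rows — both domains' unlabeled covariates are legitimately
    available under covariate shift) or from the table itself. Zero-variance
    features are dropped with a warning. The statistics are retained on the
    result so the same transform can be reapplied; note that reapplying
    :func:`standardize` itself re-centers rather than acting as an identity.
    """
    ref = stats_from if stats_from is not None else table
    mean = ref.features.mean(axis=0)
    std = ref.features.std(axis=0, ddof=0)
    keep = std > 1e-12
    if not keep.all():
        dropped = [n for n, k in zip(ref.feature_names, keep) if not k]
        logger.warning("dropping zero-variance features: %s", dropped)
    if not keep.any():
        raise DegenerateDataError("all features have zero variance")
    feats = (table.features[:, keep] - mean[keep]) / std[keep]
    names = [n for n, k in zip(table.feature_names, keep) if k]
    return FeatureTable(
        feats, table.labels, table.years, names,
        transform={"mean": mean[keep], "std": std[keep], "kept": keep},
    )


def project_pca(
    table: FeatureTable, n_components: Union[int, str] = "all", seed: int = 0
) -> FeatureTable:
    """Deterministic PCA projection with a fixed sign convention.

    ``n_components`` in {2, 3, 4, ..., d} or "all" (an orthogonal rotation
    with zero reconstruction error). Each component's sign is fixed so its
    largest-|loading| entry is positive, making repeated runs bit-identical.
    """
    if n_components == "all":
        k = table.d
    else:
        k = int(n_components)
    if not 1 <= k <= table.d:
        raise InvalidParameterError(f"n_components must lie in [1, {table.d}]")
    pca = PCA(n_components=k, svd_solver="full", random_state=seed)
    proj = pca.fit_transform(table.features)
    # Sign convention: flip components whose largest-magnitude loading is negative.
    flips = np.sign(
        pca.components_[np.arange(k), np.abs(pca.components_).argmax(axis=1)]
    )
    flips[flips == 0] = 1.0
    proj = proj * flips
    names = [f"pc{i+1}" for i in range(k)]
    return FeatureTable(proj, table.labels, table.years, names)


def temporal_split(
    table: FeatureTable,
    cut_year: int,
    validate_clustering: bool = True,
    r_max: float = 5.0,
    seed: int = 0,
) -> tuple[FeatureTable, FeatureTable]:
    """Split rows by year and orient so the more-clustered side is the source.

    Rows with year <= cut_year form the source candidate, later rows the
    target candidate; the assignment is validated (or swapped) by the
    clustering diagnostic when requested.
    """
    if table.years is None:
        raise InvalidParameterError("temporal_split requires a year column")
    early = table.years <= cut_year
    if not early.any() or early.all():
        raise DegenerateDataError(
            f"cut_year {cut_year} leaves one side of the split empty"
        )

    def subset(mask: np.ndarray) -> FeatureTable:
        return FeatureTable(
            table.features[mask], table.labels[mask],
            table.years[mask], list(table.feature_names),
        )

    source, target = subset(early), subset(~early)
    if validate_clustering:
        feats = np.vstack([source.features, target.features])
        lo, hi = feats.min(axis=0), feats.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        bounds = np.column_stack([lo, lo + span])
        order = rank_by_clustering(
            [
                PointSet(source.features, domain_tag="source"),
                PointSet(target.features, domain_tag="target"),
            ],
            r_max=r_max,
            seed=seed,
            bounds=bounds,
        )
        if order[0] == 1:  # the late-years side is the more clustered one
            logger.info("temporal_split: swapping sides by clustering diagnostic")
            source, target = target, source
    return source, target
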