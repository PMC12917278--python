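"""Prepare external tabular data for the estimators.

Real point data (e.g. species occurrences with environmental covariates)
arrives as a CSV with feature columns f1..fD, a binary label y, and a year.
The pipeline standardizes features, optionally projects onto principal
components, splits temporally, and lets the clustering diagnostic decide
which side plays the clustered source role.
"""

import numpy as np
import pandas as pd

from shiftrisk import project_pca, read_feature_csv, standardize, temporal_split

# Build a small synthetic stand-in for a downloaded occurrence table.
rng = np.random.default_rng(0)
n = 400
years = rng.choice([1995, 2000, 2010, 2015], size=n)
clustered = years > 2005  # later surveys concentrate around a few sites
centers = rng.uniform(-2, 2, size=(4, 2))
feats = np.where(
    clustered[:, None],
    centers[rng.integers(0, 4, n)] + 0.1 * rng.normal(size=(n, 2)),
    rng.uniform(-3, 3, size=(n, 2)),
)
df = pd.DataFrame({"f1": feats[:, 0], "f2": feats[:, 1],
                   "y": rng.integers(0, 2, n), "year": years})
df.to_csv("/tmp/occurrences.csv", index=False)

table = read_feature_csv("/tmp/occurrences.csv")
table = standardize(table)
table = project_pca(table, n_components="all")
source, target = temporal_split(table, cut_year=2005, r_max=1.0, seed=0)

print(f"rows: {table.n}, features after PCA: {table.feature_names}")
print(f"source (clustered side): {source.n} rows, "
      f"years {sorted({int(y) for y in source.years})}")
print(f"target:                  {target.n} rows, "
      f"years {sorted({int(y) for y in target.years})}")
print("\nsource/target PointSets feed directly into compute_weights / run_trial:")
print(source.to_pointset("source").coords.shape,
      target.to_pointset("target").coords.shape)
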