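# Methods

This note documents the statistical model, the synthetic data generator, the
estimators, the numerical choices, and the limitations of `shiftrisk`. It
makes no empirical claims beyond what the test suite and
`scripts/acceptance.py` compute.

## Problem setting

A fixed model is trained on labeled draws from a source density `g(x)` on a
spatial/feature domain and deployed on a target density `p(x)` on the same
domain. Under covariate shift the conditional label mechanism is unchanged;
only the input density moves. The quantity of interest is the target risk

```
R = ∫ e(x) p(x) dx
```

where `e(x) ≥ 0` is the model's per-point error (squared error against a
known response surface in the regression track, per-point log-loss in the
classification track). The Monte-Carlo benchmark (`gt`) averages errors over
labeled target test points and exists only to score the estimators; every
estimator sees source labels and *unlabeled* coordinates from both domains.

All estimators share the form `R̂ = (1/n) Σ_i w_i e(x_i)` over `n` source
test points:

* **nw** — `w ≡ 1`. Consistent for the *source* risk, biased under shift.
* **iw** — `w_i = p̂(x_i)/max(ĝ(x_i), floor)` with Gaussian KDEs fitted on
  the two training partitions. Full bandwidth matrices by Scott's rule,
  `H = Σ̂ · n^(−2/(d+4))` (sample covariance, ddof=1). The floor
  (default `1e−12`) keeps weights finite when the source density collapses in
  regions the target occupies — the *weight explosion* pathology is then
  visible as very large but finite weights; the number of floored
  denominators is logged and recorded in the weight diagnostics.
* **classifier** — a gradient-boosted source-vs-target discriminator turns
  its posterior into the ratio via Bayes' rule,
  `w_i = (n_g/n_p)(1/P̂(source|x_i) − 1)`, clipped to `[0, B]`.
* **kmm** — kernel mean matching; see below.

Accuracy over repeated trials is summarized by
`MAPE = 100·mean|gt−est|/gt`, `RMSE = sqrt(mean (gt−est)²)`, and
`RMSPE = 100·sqrt(mean ((gt−est)/gt)²)`. Percentage metrics are undefined for
a ~zero ground truth; a guard raises instead of dividing by zero.

## Kernel mean matching

With the RBF kernel `k(x,z) = exp(−‖x−z‖²/(2σ²))`, KMM picks weights that
minimize the squared maximum mean discrepancy between the weighted source
empirical embedding and the target embedding:

```
min_w  (1/n_g²) wᵀK w − (2/n_g) κᵀw
s.t.   0 ≤ w_j ≤ B,   Σ_j w_j = n_g
```

where `K` is the source–source Gram matrix and
`κ_i = (1/n_p) Σ_j k(x_i, z_j)` is the mean similarity of source point `i`
to the target sample. The kernel bandwidth is the median heuristic
`σ² = median‖x_i−x_j‖² / ln n` over source test points (self-pairs excluded,
natural log; if all points coincide, `σ² = 1` as a documented fallback). The
weight bound defaults to `B = 1000`; `B ≥ 1` is required so the all-ones
vector stays feasible, which guarantees the solution's objective never
exceeds the unweighted one.

### QP solver

No QP library is assumed; the program is solved in-package by FISTA
(accelerated projected gradient) because the feasible set — a box
intersected with a simplex-sum constraint ("capped simplex") — admits an
exact Euclidean projection:

* **Projection.** `w = clip(v − τ, 0, B)` where the scalar `τ` solves a
  monotone piecewise-linear equation; `τ` is located exactly by sorting the
  `2n` breakpoints (`O(n log n)`), with a bisection fallback for degenerate
  tie patterns and a final polish of the sum constraint on interior
  coordinates.
* **Step size.** `1/L` with `L = 2λ_max(K)/n_g²`, from a dense symmetric
  eigensolve for `n ≤ 400` and power iteration above.
* **Restart and safeguard.** Gradient-scheme adaptive restart drops the
  momentum when it points against progress; the best objective seen is
  tracked so the returned point never regresses behind the feasible
  all-ones start.
* **Convergence.** The projected-gradient fixed-point residual is checked
  every 10 iterations against `tol = 1e−8` (`status = "optimal"`). At the
  iteration cap (default 4,000) a residual below `1e−4` is accepted with a
  logged warning (`status = "max_iter"`; at that residual the weight error is
  negligible against the Monte-Carlo noise of a trial); larger residuals
  raise a solver error. Constraints are enforced by a final exact projection.

The solver is validated in the test suite against exhaustive grid search on
small well-conditioned instances and against the closed-form two-point case,
and the MMD-reduction property (weighted MMD ≤ unweighted MMD) is asserted on
every synthetic scenario.

## Synthetic shift scenarios

Point clouds live in `[0, 100]^d` (any `d ≥ 1`; the benchmark uses 2–4).
Clustered clouds are Gaussian mixtures with 30 components by default:
centers uniform in the (possibly cropped) box, eigenvalues i.i.d.
`U(0.2·σ_max, σ_max)` rotated by a random orthogonal matrix, and rejection
re-sampling so every point lies in the box. `σ_max` (the largest eigenvalue
of any component covariance, squared domain units) controls spread: 10–50
gives tight distinct clusters, 400 a diffuse cloud, and `"uniform"` replaces
the mixture with complete spatial randomness. Ten named bidirectional
scenarios emulate survey biases:

| scenario | source → target |
| --- | --- |
| domain_truncation_{cropped_to_full, full_to_cropped} | one domain restricted to `x₂ <` midpoint |
| mode_{expansion, contraction} | single centered mode ↔ 30 scattered clusters |
| correlation_{shift, restoration} | shared eigenvalues, diagonal ↔ rotated covariance (σ_max = 150) |
| variance_{focusing, extrapolation} | σ_max 400 ↔ 50 |
| support_mismatch_{uniform_to_gmm, gmm_to_uniform} | uniform ↔ clustered GMM (σ_max = 50) |

The regression response surface is a mixture of 10 isotropic Gaussian bumps
(amplitudes `U(−1,1)`, widths `U(5,25)` domain units, centers uniform),
giving the fitted model spatially varying error; the classification track
draws Bernoulli labels with `P(y=1|x) = sigmoid(gain · f(x))`. Benchmark
defaults: 70/30 train/test split per domain, default scikit-learn
gradient-boosted models, no hyperparameter tuning anywhere.

Every stochastic stage (centers, covariances, points, true function, splits,
model, trial index) draws from its own named substream derived from the
master seed, so runs are bit-reproducible and changing one stage never
perturbs another.

## Clustering diagnostic (LCF)

For radius `r`, `LCF(r) = (N̄_obs − N̄_csr)/(N̄_obs + N̄_csr)` contrasts the
observed mean neighbor count with a seeded uniform (CSR) reference in the
same bounds (default 100 replicates). The statistic is bounded in `[−1, 1]`
and scale-invariant when coordinates, bounds and radii are scaled together;
the trapezoidal area over `(0, r_max]` (default `r_max = 25` for the
synthetic box) summarizes clustering intensity. `rank_by_clustering` orders
datasets by this area and drives the source/target orientation of real-data
temporal splits: the more clustered side plays the source.

## Real-data ingestion

`read_feature_csv` expects prepared numeric tables (`f1..fD`, binary `y`,
optional `year`), dropping incomplete rows with a warning. `standardize`
centers/scales (statistics either from the table itself or from a reference
table; zero-variance columns dropped), `project_pca` offers a deterministic
PCA with a fixed sign convention (full-rank projection is an orthogonal
rotation, which the kernel pipeline is invariant to — a property asserted in
the tests), and `temporal_split` cuts by year and validates the orientation
with the LCF. Raw-data acquisition (downloads, thinning, CRS handling) is
out of scope.

## Problem sizes and runtime

The package's benchmark configurations are chosen for a single CPU:
N = 2,000 points per domain and 20 repetitions per scenario (the full
ten-scenario sweep runs in a few minutes; the 4-D quantitative targets in
under a minute). Larger configurations (N = 10,000, 100 repetitions) are a
matter of flags, not code.

## Limitations

* KDE-based importance weighting degrades quickly beyond d ≈ 4 and is the
  documented weak point under support mismatch; it is retained as the
  baseline it is.
* The KMM weight bound `B` caps how much mass one source point can carry;
  when the target occupies regions the source essentially never visits, all
  estimators (including KMM) underestimate the risk contributed there, and
  the residual bias shrinks with sample size.
* The Monte-Carlo ground truth is itself an estimate; metrics at small
  repetition counts carry sampling noise (the dispersion columns of the
  metrics table quantify it).
* The loose-convergence path of the solver accepts residuals in
  `(1e−8, 1e−4]` at the iteration cap; callers needing certified optima can
  raise `max_iter`.
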