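"""Weight estimation: KDE ratio, classifier ratio, capped-simplex projection, KMM."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr, truncnorm

from shiftrisk import (
    BandwidthMatrix,
    KernelConfig,
    PointSet,
    build_kmm_problem,
    classifier_weights,
    empirical_mmd2,
    fit_domain_classifier,
    iw_weights,
    kde_eval,
    kde_fit,
    kmm_objective,
    median_sigma,
    rbf_gram,
    scott_bandwidth,
    solve_kmm,
)
from shiftrisk.weights import DomainClassifier, project_capped_simplex
from shiftrisk.exceptions import (
    DegenerateDataError,
    InvalidParameterError,
    ShapeError,
)


# ---------------------------------------------------------------- bandwidths

def test_bandwidth_matrix_requires_spd():
    with pytest.raises(InvalidParameterError):
        BandwidthMatrix(np.array([[1.0, 2.0], [0.0, 1.0]]))  # asymmetric
    with pytest.raises(DegenerateDataError):
        BandwidthMatrix(np.array([[1.0, 0.0], [0.0, -1.0]]))  # indefinite


def test_scott_bandwidth_is_scale_equivariant():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(60, 2))
    H1 = scott_bandwidth(PointSet(X)).H
    H2 = scott_bandwidth(PointSet(3.0 * X)).H
    np.testing.assert_allclose(H2, 9.0 * H1, rtol=1e-12)


def test_scott_bandwidth_shrinks_with_sample_size():
    # Two samples engineered to share the identical sample covariance so only
    # the n^(-2/(d+4)) factor differs: H(2n) / H(n) = 2^(-2/(d+4)).
    rng = np.random.default_rng(1)

    def with_unit_cov(n):
        X = rng.normal(size=(n, 2))
        X -= X.mean(axis=0)
        L = np.linalg.cholesky(np.cov(X, rowvar=False))
        return PointSet(X @ np.linalg.inv(L).T)

    H_n = scott_bandwidth(with_unit_cov(64)).H
    H_2n = scott_bandwidth(with_unit_cov(128)).H
    np.testing.assert_allclose(H_2n, 2.0 ** (-2.0 / 6.0) * H_n, rtol=1e-9, atol=1e-12)


def test_scott_bandwidth_rejects_degenerate_data():
    with pytest.raises(DegenerateDataError):
        scott_bandwidth(PointSet(np.zeros((5, 2)) + 1.0))  # zero variance
    with pytest.raises(DegenerateDataError):
        scott_bandwidth(PointSet(np.array([[0.0, 0.0]])))  # single point


# ---------------------------------------------------------------- KDE

def test_kde_at_single_train_point_is_gaussian_normalizer():
    ps = PointSet(np.array([[3.0, -1.0]]))
    model = kde_fit(ps, BandwidthMatrix(np.eye(2)))
    val = kde_eval(model, ps.coords)[0]
    np.testing.assert_allclose(val, 1.0 / (2.0 * np.pi), rtol=1e-12)


def test_kde_integrates_to_one_on_a_grid():
    rng = np.random.default_rng(2)
    ps = PointSet(rng.normal(0.0, 1.0, size=(40, 1)))
    model = kde_fit(ps, scott_bandwidth(ps))
    grid = np.linspace(-10, 10, 4001)[:, None]
    mass = np.trapezoid(kde_eval(model, grid), grid[:, 0])
    np.testing.assert_allclose(mass, 1.0, atol=1e-6)


def test_kde_matches_full_bandwidth_formula():
    rng = np.random.default_rng(3)
    train = rng.normal(size=(15, 2))
    H = np.array([[2.0, 0.5], [0.5, 1.0]])
    model = kde_fit(PointSet(train), BandwidthMatrix(H))
    x = rng.normal(size=(7, 2))
    Hinv = np.linalg.inv(H)
    norm = 1.0 / (2.0 * np.pi * np.sqrt(np.linalg.det(H)))
    expected = np.array(
        [
            np.mean([norm * np.exp(-0.5 * (xi - t) @ Hinv @ (xi - t)) for t in train])
            for xi in x
        ]
    )
    np.testing.assert_allclose(kde_eval(model, x), expected, rtol=1e-10)


def test_kde_rejects_mismatched_dimension():
    model = kde_fit(PointSet(np.zeros((3, 2))), BandwidthMatrix(np.eye(2)))
    with pytest.raises(ShapeError):
        kde_eval(model, np.zeros((4, 3)))


# ---------------------------------------------------------------- IW route

def test_iw_weights_recover_density_ratio_ranking():
    # 1-D truncated Gaussians with known densities: the KDE ratio should
    # reproduce the ordering of the true ratio p/g over source points.
    rng = np.random.default_rng(4)
    a_g, b_g = (0 - 50) / 15, (100 - 50) / 15
    a_p, b_p = (0 - 60) / 15, (100 - 60) / 15
    xg = truncnorm.rvs(a_g, b_g, loc=50, scale=15, size=500, random_state=rng)
    xp = truncnorm.rvs(a_p, b_p, loc=60, scale=15, size=500, random_state=rng)
    src_train, src_eval = PointSet(xg[:350, None]), PointSet(xg[350:, None])
    tgt_train = PointSet(xp[:350, None])
    w = iw_weights(
        kde_fit(tgt_train, scott_bandwidth(tgt_train)),
        kde_fit(src_train, scott_bandwidth(src_train)),
        src_eval,
    )
    x = src_eval.coords[:, 0]
    true_ratio = truncnorm.pdf(x, a_p, b_p, loc=60, scale=15) / truncnorm.pdf(
        x, a_g, b_g, loc=50, scale=15
    )
    rho = spearmanr(w.values, true_ratio).statistic
    assert rho > 0.9


def test_iw_weights_floor_and_diagnostics():
    train = PointSet(np.linspace(0, 1, 30)[:, None])
    dens = kde_fit(train, BandwidthMatrix(np.array([[1e-4]])))
    far = PointSet(np.array([[1000.0]]))  # source density underflows to 0
    w = iw_weights(dens, dens, far, floor=1e-12)
    assert w.diagnostics["floored_count"] == 1
    assert np.isfinite(w.values[0])


# ---------------------------------------------------------------- classifier route

def test_classifier_weights_follow_bayes_rule_exactly():
    # With a known posterior the weight must equal (n_g/n_p)(1/P(g|x) - 1).
    clf = DomainClassifier(
        posterior=lambda x: 1.0 / (1.0 + np.exp(-x[:, 0])),  # P(target | x)
        prior_g=2 / 3,
        prior_p=1 / 3,
        n_g_train=100,
        n_p_train=50,
    )
    x = np.linspace(-2, 2, 9)[:, None]
    w = classifier_weights(clf, PointSet(x), clip_max=1e6)
    p_tgt = 1.0 / (1.0 + np.exp(-x[:, 0]))
    expected = (100 / 50) * (1.0 / (1.0 - p_tgt) - 1.0)
    np.testing.assert_allclose(w.values, expected, rtol=1e-9)


def test_classifier_weights_clip_at_bound():
    clf = DomainClassifier(
        posterior=lambda x: np.ones(x.shape[0]),  # P(source|x) = 0 everywhere
        prior_g=0.5, prior_p=0.5, n_g_train=10, n_p_train=10,
    )
    w = classifier_weights(clf, PointSet(np.zeros((3, 1))), clip_max=1000.0)
    np.testing.assert_array_equal(w.values, np.full(3, 1000.0))


def test_fitted_domain_classifier_separates_disjoint_clouds():
    rng = np.random.default_rng(5)
    src = PointSet(rng.normal(0.0, 1.0, size=(150, 2)), domain_tag="source")
    tgt = PointSet(rng.normal(8.0, 1.0, size=(150, 2)), domain_tag="target")
    clf = fit_domain_classifier(src, tgt, seed=0)
    assert clf.prob_target(np.array([[8.0, 8.0]]))[0] > 0.9
    assert clf.prob_target(np.array([[0.0, 0.0]]))[0] < 0.1


# ---------------------------------------------------------------- kernel pieces

def test_median_sigma_exact_small_case():
    pts = PointSet(np.array([[0.0], [1.0], [3.0]]))
    np.testing.assert_allclose(median_sigma(pts), 4.0 / np.log(3.0), rtol=1e-12)


def test_median_sigma_identical_points_fall_back():
    assert median_sigma(PointSet(np.zeros((5, 2)))) == 1.0


def test_rbf_gram_values_and_symmetry():
    X = PointSet(np.array([[0.0], [2.0]]))
    K = rbf_gram(X, X, sigma2=2.0)
    np.testing.assert_allclose(np.diag(K), [1.0, 1.0])
    np.testing.assert_allclose(K[0, 1], np.exp(-1.0), rtol=1e-12)
    with pytest.raises(InvalidParameterError):
        rbf_gram(X, X, sigma2=0.0)


# ---------------------------------------------------------------- projection

def _oracle_projection(v, total, cap, iters=200):
    lo, hi = float(v.min()) - cap, float(v.max())
    for _ in range(iters):
        tau = 0.5 * (lo + hi)
        if np.clip(v - tau, 0.0, cap).sum() > total:
            lo = tau
        else:
            hi = tau
    return np.clip(v - 0.5 * (lo + hi), 0.0, cap)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    seed=st.integers(min_value=0, max_value=10_000),
    n=st.integers(min_value=1, max_value=50),
    cap=st.floats(min_value=0.1, max_value=100.0),
    scale=st.floats(min_value=0.01, max_value=100.0),
)
def test_projection_matches_bisection_oracle(seed, n, cap, scale):
    rng = np.random.default_rng(seed)
    v = rng.normal(scale=scale, size=n)
    total = float(rng.uniform(0.0, n * cap))
    w = project_capped_simplex(v, total, cap)
    assert abs(w.sum() - total) < 1e-8 * max(1.0, total)
    assert np.all(w >= 0.0) and np.all(w <= cap + 1e-12)
    np.testing.assert_allclose(w, _oracle_projection(v, total, cap), atol=1e-6)


def test_projection_handles_ties_exactly():
    v = np.array([1.0, 1.0, 1.0, 1.0])
    w = project_capped_simplex(v, 2.0, 1.0)
    np.testing.assert_allclose(w, np.full(4, 0.5), atol=1e-12)


def test_projection_rejects_empty_polytope():
    with pytest.raises(InvalidParameterError):
        project_capped_simplex(np.ones(3), total=10.0, cap=1.0)


# ---------------------------------------------------------------- KMM

def test_kmm_two_point_example_has_closed_form_solution():
    # Source {0, 1}, target {0}, k(x,z) = exp(-(x-z)^2): the matching
    # objective reduces to f(t) = t(1-e^{-1}) * t/2 ... with minimizer w=(2,0).
    src = PointSet(np.array([[0.0], [1.0]]))
    tgt = PointSet(np.array([[0.0]]))
    problem = build_kmm_problem(src, tgt, KernelConfig(sigma2=0.5, B=2.0))
    np.testing.assert_allclose(problem.kappa, [1.0, np.exp(-1.0)], rtol=1e-12)
    w = solve_kmm(problem)
    np.testing.assert_allclose(w.values, [2.0, 0.0], atol=1e-6)


def test_kmm_respects_constraints_and_beats_uniform(small_pair):
    src, tgt = small_pair
    sigma2 = median_sigma(src)
    problem = build_kmm_problem(src, tgt, KernelConfig(sigma2=sigma2, B=1000.0))
    w = solve_kmm(problem)
    np.testing.assert_allclose(w.values.sum(), src.n, rtol=1e-9)
    assert np.all(w.values >= 0.0) and np.all(w.values <= 1000.0 + 1e-9)
    ones = np.ones(src.n)
    assert kmm_objective(problem, w.values) <= kmm_objective(problem, ones) + 1e-12
    assert w.diagnostics["solver_status"] in ("optimal", "max_iter")


def test_kmm_upweights_target_dense_regions():
    rng = np.random.default_rng(6)
    # Bimodal source; target sits entirely on the right mode.
    left = rng.normal(10.0, 1.0, size=(100, 1))
    right = rng.normal(30.0, 1.0, size=(100, 1))
    src = PointSet(np.vstack([left, right]))
    tgt = PointSet(rng.normal(30.0, 1.0, size=(150, 1)), domain_tag="target")
    problem = build_kmm_problem(src, tgt, KernelConfig(sigma2=median_sigma(src)))
    w = solve_kmm(problem).values
    assert w[100:].mean() > 3.0 * w[:100].mean()


def test_kernel_config_validates_parameters():
    with pytest.raises(InvalidParameterError):
        KernelConfig(sigma2=-1.0)
    with pytest.raises(InvalidParameterError):
        KernelConfig(sigma2=1.0, B=0.5)  # all-ones must stay feasible


# ---------------------------------------------------------------- MMD

def test_mmd2_is_nonnegative_and_zero_on_identical_sets():
    rng = np.random.default_rng(7)
    X = PointSet(rng.normal(size=(40, 2)))
    assert abs(empirical_mmd2(X, X, sigma2=1.0)) < 1e-12
    Y = PointSet(rng.normal(3.0, 1.0, size=(40, 2)), domain_tag="target")
    assert empirical_mmd2(X, Y, sigma2=1.0) > 0.0


def test_kmm_weights_reduce_mmd_on_shifted_clouds():
    rng = np.random.default_rng(8)
    src = PointSet(rng.normal(0.0, 2.0, size=(120, 2)))
    tgt = PointSet(rng.normal(1.5, 1.0, size=(120, 2)), domain_tag="target")
    sigma2 = median_sigma(src)
    w = solve_kmm(build_kmm_problem(src, tgt, KernelConfig(sigma2=sigma2))).values
    assert empirical_mmd2(src, tgt, sigma2, w) <= empirical_mmd2(src, tgt, sigma2)
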