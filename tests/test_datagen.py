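"""Scenario generator: bounds, determinism, recipe structure, splits, CSV I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shiftrisk import (
    PointSet,
    SCENARIO_IDS,
    ScenarioConfig,
    make_scenario,
    make_true_function,
    sample_gmm,
    sample_uniform,
    split,
)
from shiftrisk.datagen import read_points_csv, write_points_csv
from shiftrisk.exceptions import (
    CannotSplitError,
    InvalidParameterError,
    ShapeError,
    UnknownScenarioError,
)


# ---------------------------------------------------------------- PointSet

def test_pointset_validates_shapes_and_tags():
    with pytest.raises(ShapeError):
        PointSet(np.ones((3, 2)), labels=np.ones(2))
    with pytest.raises(InvalidParameterError):
        PointSet(np.array([[np.nan, 0.0]]))
    with pytest.raises(InvalidParameterError):
        PointSet(np.ones((2, 2)), domain_tag="elsewhere")


# ---------------------------------------------------------------- sampling

def test_gmm_points_stay_inside_bounds():
    ps = sample_gmm(2, 500, sigma_max=400.0, seed=3)
    assert ps.coords.shape == (500, 2)
    assert np.all(ps.coords >= 0.0) and np.all(ps.coords <= 100.0)


def test_gmm_is_deterministic_given_seed():
    a = sample_gmm(3, 200, sigma_max=50.0, seed=9)
    b = sample_gmm(3, 200, sigma_max=50.0, seed=9)
    np.testing.assert_array_equal(a.coords, b.coords)
    c = sample_gmm(3, 200, sigma_max=50.0, seed=10)
    assert not np.array_equal(a.coords, c.coords)


def test_vanishing_covariance_collapses_points_onto_centers():
    # With sigma_max ~ 0 every sampled point coincides (to float precision)
    # with one of the component centers.
    ps = sample_gmm(2, 5, sigma_max=1e-9, n_components=5, seed=7)
    from shiftrisk._rng import substream

    true_centers = substream(7, "centers").uniform(0.0, 100.0, size=(5, 2))
    dists = np.linalg.norm(
        ps.coords[:, None, :] - true_centers[None, :, :], axis=2
    ).min(axis=1)
    assert np.all(dists < 1e-3)


def test_uniform_sampler_fills_the_box():
    ps = sample_uniform(2, 4000, seed=1)
    # Mean near the center and coverage of all four quadrants.
    assert np.all(np.abs(ps.coords.mean(axis=0) - 50.0) < 3.0)
    q = (ps.coords > 50.0)
    for pattern in [(0, 0), (0, 1), (1, 0), (1, 1)]:
        assert np.any((q[:, 0] == pattern[0]) & (q[:, 1] == pattern[1]))


def test_gmm_rejects_bad_parameters():
    with pytest.raises(InvalidParameterError):
        sample_gmm(2, 10, sigma_max=-1.0)
    with pytest.raises(InvalidParameterError):
        sample_gmm(2, 0, sigma_max=50.0)
    with pytest.raises(InvalidParameterError):
        sample_uniform(2, 10, bounds=(5.0, 5.0))


def test_smaller_sigma_max_gives_tighter_clusters():
    tight = sample_gmm(2, 1500, sigma_max=10.0, seed=4)
    loose = sample_gmm(2, 1500, sigma_max=400.0, seed=4)
    # Mean nearest-neighbor distance is smaller for the clustered cloud.
    from scipy.spatial import cKDTree

    def mean_nn(c):
        d, _ = cKDTree(c).query(c, k=2)
        return d[:, 1].mean()

    assert mean_nn(tight.coords) < mean_nn(loose.coords)


# ---------------------------------------------------------------- scenarios

def test_scenario_registry_contains_ten_bidirectional_recipes():
    assert len(SCENARIO_IDS) == 10
    assert "support_mismatch_gmm_to_uniform" in SCENARIO_IDS
    assert "domain_truncation_cropped_to_full" in SCENARIO_IDS


@pytest.mark.parametrize("sid", SCENARIO_IDS)
def test_every_scenario_yields_tagged_in_bounds_pairs(sid):
    cfg = ScenarioConfig(scenario_id=sid, d=2, n_points=120, seed=5)
    src, tgt = make_scenario(cfg)
    assert src.domain_tag == "source" and tgt.domain_tag == "target"
    assert src.n == tgt.n == 120
    for ps in (src, tgt):
        assert np.all(ps.coords >= 0.0) and np.all(ps.coords <= 100.0)


def test_unknown_scenario_raises():
    with pytest.raises(UnknownScenarioError):
        make_scenario(ScenarioConfig(scenario_id="nope", n_points=50))


def test_domain_truncation_restricts_the_second_axis():
    cfg = ScenarioConfig(
        scenario_id="domain_truncation_cropped_to_full", d=2, n_points=300, seed=2
    )
    src, tgt = make_scenario(cfg)
    assert src.coords[:, 1].max() <= 50.0
    assert tgt.coords[:, 1].max() > 50.0


def test_scenario_pairs_use_independent_draws():
    cfg = ScenarioConfig(scenario_id="variance_focusing", d=2, n_points=100, seed=6)
    src, tgt = make_scenario(cfg)
    assert not np.array_equal(src.coords, tgt.coords)


def test_correlation_shift_changes_only_the_correlation():
    cfg = ScenarioConfig(scenario_id="correlation_shift", d=2, n_points=6000, seed=8)
    src, tgt = make_scenario(cfg)
    corr_s = np.corrcoef(src.coords, rowvar=False)[0, 1]
    # The diagonal-covariance source is (near-)uncorrelated; the rotated
    # target departs visibly unless the random rotation is axis-aligned.
    assert abs(corr_s) < 0.1


# ---------------------------------------------------------------- true function

def test_true_function_is_smooth_bounded_and_deterministic():
    f1 = make_true_function(2, seed=3)
    f2 = make_true_function(2, seed=3)
    x = np.random.default_rng(0).uniform(0, 100, size=(50, 2))
    np.testing.assert_array_equal(f1(x), f2(x))
    # A sum of 10 bumps with |amplitude| <= 1 is bounded by 10.
    assert np.all(np.abs(f1(x)) <= 10.0)


def test_true_function_peaks_at_a_bump_center():
    f = make_true_function(2, seed=3)
    k = int(np.argmax(np.abs(f.amplitudes)))
    c = f.centers[k]
    val_center = abs(f(c[None, :])[0])
    far = c + 4.0 * f.widths.max()
    assert val_center > abs(f(far[None, :])[0])


# ---------------------------------------------------------------- split

@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    n=st.integers(min_value=10, max_value=300),
    frac=st.floats(min_value=0.1, max_value=0.9),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
)
def test_split_is_a_disjoint_exhaustive_partition(n, frac, seed):
    coords = np.arange(n, dtype=float)[:, None]
    ps = PointSet(coords, labels=np.arange(n, dtype=float))
    train, test = split(ps, frac, seed)
    assert train.n == int(np.floor(frac * n))
    assert train.n + test.n == n
    merged = np.sort(np.concatenate([train.coords[:, 0], test.coords[:, 0]]))
    np.testing.assert_array_equal(merged, coords[:, 0])
    # labels travel with their rows
    np.testing.assert_array_equal(train.labels, train.coords[:, 0])


def test_split_rejects_degenerate_fractions():
    ps = PointSet(np.arange(4, dtype=float)[:, None])
    with pytest.raises(InvalidParameterError):
        split(ps, 1.0, 0)
    with pytest.raises(CannotSplitError):
        split(ps, 0.01, 0)  # floor(0.04) = 0 train rows


# ---------------------------------------------------------------- CSV round trip

def test_points_csv_round_trip(tmp_path, small_pair):
    src, _ = small_pair
    labeled = src.with_labels(np.arange(src.n, dtype=float))
    path = tmp_path / "pts.csv"
    write_points_csv(labeled, path)
    back = read_points_csv(path)
    np.testing.assert_allclose(back.coords, labeled.coords)
    np.testing.assert_allclose(back.labels, labeled.labels)
    assert back.domain_tag == labeled.domain_tag
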