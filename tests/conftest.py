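"""Shared fixtures: small, fast point sets and scenario configurations."""

from __future__ import annotations

import numpy as np
import pytest

from shiftrisk import PointSet, ScenarioConfig, make_scenario, make_true_function


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20261002)


@pytest.fixture(scope="session")
def small_pair():
    """A small clustered-source / uniform-target pair (d=2, N=400)."""
    cfg = ScenarioConfig(
        scenario_id="support_mismatch_gmm_to_uniform", d=2, n_points=400, seed=11
    )
    return make_scenario(cfg)


@pytest.fixture(scope="session")
def true_fn_2d():
    return make_true_function(2, seed=11)


@pytest.fixture()
def unit_square_points(rng):
    return PointSet(rng.uniform(0.0, 1.0, size=(40, 2)))
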