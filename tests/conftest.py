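"""Shared fixtures.

Heavy artifacts (the default synthetic dataset and its group connectome)
are session-scoped so the acceptance tests can share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from stemcortex import connectome as conn
from stemcortex import simulate as sim


@pytest.fixture(scope="session")
def default_model():
    return sim.GenerativeModel(seed=0)


@pytest.fixture(scope="session")
def default_scheme(default_model):
    return sim.make_scheme(default_model)


@pytest.fixture(scope="session")
def default_truth(default_model):
    return sim.ground_truth(default_model)


@pytest.fixture(scope="session")
def default_group(default_model, default_scheme):
    subjects = sim.simulate_timeseries(default_model, default_scheme)
    return conn.group_average([conn.build_fc(ts, default_scheme)
                               for ts in subjects])


@pytest.fixture(scope="session")
def small_model():
    """A reduced model for fast unit tests (same structure, smaller sizes)."""
    return sim.GenerativeModel(seed=3, n_cortex=80, n_brainstem=20,
                               n_midline=4, K=4, n_subjects=4,
                               n_timepoints=240, n_distance_factors=12,
                               n_receptor_maps=6, n_term_maps=15)


@pytest.fixture(scope="session")
def small_scheme(small_model):
    return sim.make_scheme(small_model)


@pytest.fixture(scope="session")
def small_group(small_model, small_scheme):
    subjects = sim.simulate_timeseries(small_model, small_scheme)
    return conn.group_average([conn.build_fc(ts, small_scheme)
                               for ts in subjects])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
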