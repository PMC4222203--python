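import numpy as np
import pytest

import oceansdm as o
from oceansdm import maxent as mx
from oceansdm import occurrences as occ


@pytest.fixture(scope="session")
def small_params():
    # coarse, fast ocean for unit tests
    return o.OceanParams(grid_step=6.0, lat_range=(-78.0, 78.0), seed=3)


@pytest.fixture(scope="session")
def small_ocean(small_params):
    return o.make_environment(small_params)


@pytest.fixture(scope="session")
def default_params():
    return o.OceanParams(seed=1)


@pytest.fixture(scope="session")
def ocean(default_params):
    # the 2-degree default ocean used by the recovery/seasonality criteria
    return o.make_environment(default_params)


@pytest.fixture(scope="session")
def truth():
    return o.TruthParams()


@pytest.fixture(scope="session")
def truth_maps(ocean, truth):
    return [o.true_suitability(s, truth) for s in ocean.monthly]


@pytest.fixture(scope="session")
def prepared_monthly(ocean, truth_maps):
    """Monthly-mode presence and background matrices on the default ocean."""
    occset = o.sample_presences(truth_maps, n=200, seed=7)
    ded = o.dedupe(occset.records, ocean.annual.reference(), mode="monthly")
    pres = o.extract_covariates(ded, ocean.annual, ocean.monthly, mode="monthly")
    bg = occ.sample_background_monthly(ocean.monthly, n=2000, seed=8)
    return pres, bg


@pytest.fixture(scope="session")
def monthly_model(prepared_monthly):
    pres, bg = prepared_monthly
    model = mx.fit(pres, bg, knots_per_variable=15)
    assert model.meta["converged"]
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
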