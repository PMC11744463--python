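import numpy as np
import pytest
from hypothesis import settings

from gallstone_cea import (TrialParams, UnitCostTable, generate_cohort,
                           MarkovSpec)

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def default_params() -> TrialParams:
    return TrialParams(seed=1234)


@pytest.fixture(scope="session")
def small_params() -> TrialParams:
    """Small cohort for fast structural tests."""
    return TrialParams(n_per_arm=60, n_centres=6, seed=77)


@pytest.fixture(scope="session")
def unit_costs() -> UnitCostTable:
    return UnitCostTable.default()


@pytest.fixture(scope="session")
def default_cohort(default_params):
    return generate_cohort(default_params)


@pytest.fixture(scope="session")
def small_cohort(small_params):
    return generate_cohort(small_params)


@pytest.fixture()
def lc_spec() -> MarkovSpec:
    return MarkovSpec(strategy="LC")


@pytest.fixture()
def cm_spec() -> MarkovSpec:
    return MarkovSpec(strategy="CM")
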