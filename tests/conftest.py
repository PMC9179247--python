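import numpy as np
import pytest

import pycmsy as pc
from pycmsy.scenarios import packaged_scenarios, run_scenario


@pytest.fixture(scope="session")
def fixture_data():
    """Canned 1971-2020 catch series plus the six-fleet index library."""
    return pc.study_fixture("reconstructed")


@pytest.fixture(scope="session")
def nominal_data():
    return pc.study_fixture("nominal")


@pytest.fixture(scope="session")
def cmsy_run(nominal_data):
    """One fast catch-only fit of the short-series scenario (shared)."""
    catches, lib = nominal_data
    config = next(c for c in packaged_scenarios() if c.label == "BSH_ATS_n")
    ensemble, row = run_scenario(config, catches, lib,
                                 settings=pc.SamplerSettings.fast(seed=7))
    return ensemble, row, config


@pytest.fixture(scope="session")
def bsm_run(fixture_data):
    """One fast catch+CPUE fit using the full-span index (shared)."""
    catches, lib = fixture_data
    config = next(c for c in packaged_scenarios() if c.label == "BSH_ATS_CPUE_JP")
    ensemble, row = run_scenario(config, catches, lib,
                                 settings=pc.SamplerSettings.fast(seed=7))
    return ensemble, row, config


@pytest.fixture()
def rng():
    return np.random.default_rng(20201231)
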