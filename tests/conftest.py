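"""Shared fixtures: small platform configs and cohorts that render fast.

The narrow m/z ranges keep grids small (tens of thousands of points for
the reflectron platform instead of 170k) while covering at least three
internal calibrants, so recalibration stays exercised end to end.
"""

import numpy as np
import pytest

from dualbead.synthetic import (default_effects, generate_cohort,
                                rpc18_config, wcx_config)


@pytest.fixture(scope="session")
def tiny_rpc18_config():
    # 1400-2000 Da covers the 1465.8 / 1778.1 / 1865.2 calibrants
    return rpc18_config(mz_min=1400.0, mz_max=2000.0)


@pytest.fixture(scope="session")
def tiny_wcx_config():
    # 1000-5000 Da covers the 1866.1 / 3158.0 / 4643.6 calibrants
    return wcx_config(mz_min=1000.0, mz_max=5000.0)


@pytest.fixture(scope="session")
def tiny_configs(tiny_wcx_config, tiny_rpc18_config):
    return {"WCX": tiny_wcx_config, "RPC18": tiny_rpc18_config}


@pytest.fixture(scope="session")
def tiny_effects(tiny_configs):
    return default_effects(tiny_configs, scenario="standard")


@pytest.fixture(scope="session")
def tiny_cohort(tiny_configs, tiny_effects):
    """8 cases / 8 controls x 2 replicates on both narrow platforms."""
    return generate_cohort(8, 8, 2, tiny_configs, tiny_effects, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
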