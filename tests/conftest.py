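import numpy as np
import pytest

import periopolicy as pp


@pytest.fixture(scope="session")
def default_cfg():
    return pp.default_config(n_persons=20_000)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort reused by read-only tests."""
    cfg = pp.default_config(n_persons=3000)
    return pp.simulate_cohort(cfg, seed=7)


@pytest.fixture(scope="session")
def tiny_cfg():
    return pp.TinyDGPConfig(tau=2)


@pytest.fixture(scope="session")
def tiny_panel(tiny_cfg):
    return pp.simulate_tiny(tiny_cfg, 50_000, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
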