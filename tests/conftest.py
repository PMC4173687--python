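import numpy as np
import pytest

from lingrisk.components import component_table, eligible_series, fit_growth_rate
from lingrisk.synthetic import SyntheticConfig, generate_world


@pytest.fixture(scope="session")
def tiny_config():
    """Small world: fast enough for per-test reuse, rich enough to hit
    every pipeline stage."""
    return SyntheticConfig(
        seed=11,
        grid_cols=12,
        grid_rows=8,
        n_languages=60,
        survey_min_n=4,
    )


@pytest.fixture(scope="session")
def tiny_world(tiny_config):
    return generate_world(tiny_config)


@pytest.fixture(scope="session")
def tiny_components(tiny_world):
    ests = [fit_growth_rate(s) for s in tiny_world.series if eligible_series(s)]
    return component_table(tiny_world.records, growth_estimates=ests)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
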