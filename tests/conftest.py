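import numpy as np
import pandas as pd
import pytest

from dendrosem import synthetic


@pytest.fixture(scope="session")
def small_config():
    """A reduced stand (8 trees, 85 years) for fast end-to-end checks."""
    return synthetic.SyntheticConfig(
        n_trees=8,
        year_range=(1930, 2014),
        recruit_year_range=(1930, 1945),
        n_isotope_trees=4,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return synthetic.generate_study(small_config)


@pytest.fixture(scope="session")
def default_study():
    """The full default study: 15 trees over 1895-2014, shift after 1983."""
    return synthetic.generate_study(synthetic.SyntheticConfig(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
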