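import numpy as np
import pytest

from larvataxis import ModelParams, simulate_ensemble
from larvataxis.presets import get_preset


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def uniform_field():
    return get_preset("uniform")


@pytest.fixture(scope="session")
def tilted_field():
    return get_preset("tilted_like")


@pytest.fixture(scope="session")
def pos_field():
    return get_preset("pos_like")


@pytest.fixture(scope="session")
def small_pos_ensemble(pos_field):
    """A small but well-biased ensemble reused by metrics/io tests."""
    params = ModelParams(T=10.95, beta=0.014, seed=71, max_accepted_steps=600)
    return simulate_ensemble(pos_field, params, n_larvae=6, n_replicates=3)
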