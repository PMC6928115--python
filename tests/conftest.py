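import numpy as np
import pytest

from mtssm.model import DesignSpec, ModelParams
from mtssm.simulate import default_scenario, simulate_dataset


@pytest.fixture(scope="session")
def small_scenario():
    """A small well-specified study: 5 subjects, 12 trials, 3 levels, 51 steps."""
    return default_scenario(I=5, J=12, K=3, N=51, seed=314)


@pytest.fixture(scope="session")
def small_data(small_scenario):
    Y, latent = simulate_dataset(small_scenario)
    return Y, latent


@pytest.fixture()
def categorical_design():
    return DesignSpec.from_levels(["HF"] * 2 + ["LF"] * 2 + ["NW"] * 2)


@pytest.fixture()
def default_params():
    return ModelParams(gamma=np.array([0.5, 1.0, 1.5]), kappa1=20.0, kappa2=45.0)
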