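import numpy as np
import pytest

from deepcombat import SimulationParams, make_fixture, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Small 3-batch dataset with additive + scale batch effects (fast)."""
    params = SimulationParams(n_per_batch=(50, 40, 30), p=12, latent_rank=4,
                              additive_scale=0.4, scale_effects=True,
                              male_rate=(0.55, 0.55, 0.55),
                              dx_probs=((0.3, 0.5, 0.2),) * 3)
    Y, cov, batch, truth = simulate_dataset(params, seed=11)
    return Y, cov.to_numpy(), batch, truth


@pytest.fixture(scope="session")
def additive_scale_fixture():
    Y, cov, batch, truth = make_fixture("additive+scale")
    return Y, cov.to_numpy(), batch, truth


@pytest.fixture(scope="session")
def null_fixture():
    Y, cov, batch, truth = make_fixture("null")
    return Y, cov.to_numpy(), batch, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
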