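import numpy as np
import pytest

from sepchan import SeparateChannelModel, SimConfig, simulate_two_channel


@pytest.fixture(scope="session")
def small_reference_sim():
    """A modest common-reference experiment used by several test modules."""
    cfg = SimConfig(
        G=500, n_arrays=8, conditions=("B", "C"), rho=0.7,
        d0=4.0, s0_2=0.25, prop_de=0.1, lfc=1.0, seed=314,
    )
    y, targets, truth = simulate_two_channel(cfg)
    return cfg, y, targets, truth


@pytest.fixture(scope="session")
def small_reference_model(small_reference_sim):
    _, y, targets, _ = small_reference_sim
    return SeparateChannelModel(y, targets, contrasts=["BvsC = B - C"])


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
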