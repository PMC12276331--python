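import numpy as np
import pytest

from forcekin.bond_physics import BellParams
from forcekin.simulate import SimScenario, simulate_dataset


@pytest.fixture(scope="session")
def bell_params():
    """Reference bond parameters used throughout the suite."""
    return BellParams(k_off=0.03, x_beta=0.5)


@pytest.fixture(scope="session")
def mono_dataset():
    """Monovalent simulated dataset: 6 pulling speeds x 600 curves,
    5 pN noise, no double bonds."""
    scenario = SimScenario(curves_per_condition=600, second_bond_A=0.0,
                           noise_sigma_range=(5.0, 5.0), seed=101)
    return simulate_dataset(scenario)


@pytest.fixture(scope="session")
def bivalent_dataset():
    """Bivalent simulated dataset: ~30% of bound curves carry two bonds."""
    scenario = SimScenario(curves_per_condition=600, second_bond_A=0.3,
                           second_bond_tau=0.05, noise_sigma_range=(5.0, 5.0),
                           seed=202)
    return simulate_dataset(scenario)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
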