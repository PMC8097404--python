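import numpy as np
import pytest

from pufasite.synthetic import SyntheticSystemSpec, simulate_lipid_trajectory


@pytest.fixture(scope="session")
def fixture_system():
    """The standard small synthetic fixture: 4x20-residue tetramer, 24 lipids,
    2,000 frames, seed 42."""
    spec = SyntheticSystemSpec(seed=42)
    traj, truth = simulate_lipid_trajectory(spec)
    return spec, traj, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
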