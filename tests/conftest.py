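import numpy as np
import pytest

from intergee.design import LongitudinalDataset
from intergee.simulate import SimulationDesign, simulate_dataset


@pytest.fixture
def toy_dataset():
    """2 subjects x 2 times, p=2 features, q=1 dummy."""
    rng = np.random.default_rng(7)
    y = rng.standard_normal((2, 2))
    X = rng.standard_normal((2, 2, 2))
    E = np.array([[[1.0], [1.0]], [[0.0], [0.0]]])
    return LongitudinalDataset(y=y, X=X, E=E)


@pytest.fixture
def small_sim():
    """Small but realistic simulated dataset (n=40, p=8, q=3)."""
    design = SimulationDesign(n=40, p=8, seed=11)
    data, truth = simulate_dataset(design)
    return design, data, truth
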