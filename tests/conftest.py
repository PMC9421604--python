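import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper module

from perishell.grid import VolumeGrid
from perishell.phantom import PhantomConfig, generate_case


def make_grid(values, spacing=(1.0, 1.0, 1.0), midline=None) -> VolumeGrid:
    arr = np.asarray(values)
    if midline is None:
        midline = (arr.shape[0] - 1) / 2.0
    return VolumeGrid(arr, spacing, midline_index=midline)


@pytest.fixture(scope="session")
def default_case():
    """Standard 4-cluster phantom with noise."""
    return generate_case(PhantomConfig(seed=1))


@pytest.fixture(scope="session")
def quiet_case():
    """Noise-free phantom with the default deficit + gradient."""
    return generate_case(PhantomConfig(seed=1, noise_sd=0.0, delay_sd=0.0))


@pytest.fixture(scope="session")
def null_case():
    """Noise-free phantom with no imposed effect anywhere."""
    return generate_case(PhantomConfig(seed=2, noise_sd=0.0, delay_sd=0.0,
                                       cvr_deficit=0.0, gradient_slope=0.0))
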