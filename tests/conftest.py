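import numpy as np
import pytest

from branchdyn import simulate_branching_dataset
from branchdyn.scenarios import marker_screen_config, modality_config


@pytest.fixture(scope="session")
def small_dataset():
    """A small 7-stage branching dataset (55 genes) shared across tests."""
    return simulate_branching_dataset(marker_screen_config(cells_per_stage=40, seed=123))


@pytest.fixture(scope="session")
def modality_dataset():
    """Dataset with a gene programmed bimodal pre-branch / trimodal on branch2."""
    return simulate_branching_dataset(modality_config(cells_per_stage=150, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
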