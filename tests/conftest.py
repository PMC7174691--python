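import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from cerna.synthetic import SimulationConfig, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def dataset():
    """One default synthetic dataset shared across the suite."""
    return simulate(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def lnc_sequences(dataset):
    return {t.id: t.sequence for t in dataset.lncrnas}
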