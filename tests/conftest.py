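import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from squigseg.pore_model import toy_model


@pytest.fixture(scope="session")
def toy1():
    """k=1 model: A=0, C=10, G=20, T=30, sigma=1 (widely separated levels)."""
    return toy_model(1, level_min=0.0, spacing=10.0, stdv=1.0)


@pytest.fixture(scope="session")
def toy1_noisy():
    """k=1 model with overlapping levels (spacing 5, sigma 2)."""
    return toy_model(1, level_min=0.0, spacing=5.0, stdv=2.0)


@pytest.fixture(scope="session")
def toy2():
    """k=2 model: 16 evenly spaced levels at sigma 1."""
    return toy_model(2)


@pytest.fixture(scope="session")
def toy5():
    """k=5 model: 1024 distinct evenly spaced levels at sigma 1."""
    return toy_model(5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
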