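import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ivperm.compounds import default_registry
from ivperm.synthetic import DEFAULT_CELL, DEFAULT_SCHEDULE, MembraneModel


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def cell():
    return DEFAULT_CELL


@pytest.fixture(scope="session")
def schedule():
    return DEFAULT_SCHEDULE


@pytest.fixture(scope="session")
def control_model():
    """Membrane model mirroring the free-acid / skin kinetics used in examples."""
    return MembraneModel.from_kp_lag(kp=0.74e-3, lag_time=1.17, h=0.05)
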