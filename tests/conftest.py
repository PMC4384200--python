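import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from stfield.synthetic import generate_campaign, small_scenario


@pytest.fixture(scope="session")
def small_campaign():
    """One small synthetic campaign (fixed seed) shared across tests."""
    cfg = small_scenario(seed=11)
    data, truth = generate_campaign(cfg)
    return data, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
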