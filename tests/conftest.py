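import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from discdiff.phantom import PhantomConfig
from discdiff.pipeline import make_fixtures


@pytest.fixture(scope="session")
def fixture_cohort():
    """The 6-disc CI cohort (one disc per grade plus one Modic disc)."""
    return make_fixtures(seed=7)


@pytest.fixture(scope="session")
def quiet_config():
    """Noise-free default phantom configuration."""
    return PhantomConfig(noise_sd=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
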