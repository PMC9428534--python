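import numpy as np
import pytest

from batchspawn.engine import ScenarioConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quick_scenario():
    """Factory for fast, small scenarios used by engine-level tests."""

    def make(**kw):
        kw.setdefault("burn_in_years", 60)
        kw.setdefault("initial_abundance", 400)
        kw.setdefault("burn_in_thin", 1)
        kw.setdefault("seed", 7)
        return ScenarioConfig(**kw)

    return make
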