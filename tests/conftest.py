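import numpy as np
import pytest

from pdlmech import MaterialParams
from pdlmech.synthetic import regional_presets


@pytest.fixture(scope="session")
def presets():
    """The six published regional coefficient presets."""
    return regional_presets()


@pytest.fixture
def mixed_params():
    """Symmetric two-phase toy parameters used in worked examples."""
    return MaterialParams(c1=1.0, c2=1.0, c3=1.0, c4=0.0, c5=1.0, c6=0.0, Vf=0.5)


@pytest.fixture
def param_rng():
    """Seeded generator for random-parameter property checks."""
    return np.random.default_rng(1234)


def random_params(rng, c_max=50.0):
    c = rng.uniform(-c_max, c_max, 6)
    return MaterialParams(*c, Vf=rng.uniform(0.3, 0.8))
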