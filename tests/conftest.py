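import numpy as np
import pytest

from lithocav.materials import get_material


@pytest.fixture(scope="session")
def water():
    return get_material("water", "fluid")


@pytest.fixture(scope="session")
def water_optics():
    return get_material("water", "optical")


@pytest.fixture(scope="session")
def quartz():
    return get_material("quartz", "elastic")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
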