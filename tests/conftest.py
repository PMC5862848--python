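import numpy as np
import pytest

from probescout.masses import load_modification_registry
from probescout.pipeline import make_scheme


@pytest.fixture(scope="session")
def registry():
    return load_modification_registry()


@pytest.fixture(scope="session")
def remnant(registry):
    return registry["vps_dadps"]


@pytest.fixture
def trypsin_scheme(remnant):
    return make_scheme("trypsin", ("trypsin",), remnant, step1_max_missed=0)


@pytest.fixture
def sequential_scheme(remnant):
    return make_scheme(
        "trypsin_lysC_gluC", ("trypsin", "lysC"), remnant, step2="gluC"
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
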