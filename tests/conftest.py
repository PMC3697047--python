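import numpy as np
import pytest

from tetractivity import DegenerateTetra, load_table1, load_table2
from tetractivity.features import FeatureVariant
from tetractivity.profiles import u_profile


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def table2():
    return load_table2()


@pytest.fixture(scope="session")
def planted_variant():
    """The canonical planted feature used across engine tests: RHHK with
    a centre-weighted peak profile on 22-nt fragments."""
    return FeatureVariant(DegenerateTetra("RHHK"), u_profile(0.5, 0.2, "peak", 0.0, 19))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
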