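import numpy as np
import pytest

from primerscope import default_primer_sets


@pytest.fixture(scope="session")
def primer_sets():
    return default_primer_sets()


@pytest.fixture(scope="session")
def ps16(primer_sets):
    return primer_sets["CTO189-RT1r"]


@pytest.fixture(scope="session")
def psamoa(primer_sets):
    return primer_sets["amoA1F-2R"]


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
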