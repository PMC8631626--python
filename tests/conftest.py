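import numpy as np
import pytest

from apa3utr import serpina1_region_spec


@pytest.fixture(scope="session")
def serpina1_spec():
    return serpina1_region_spec()


@pytest.fixture()
def rng():
    return np.random.default_rng(20211116)
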