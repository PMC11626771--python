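import numpy as np
import pytest

from metalgeom.library import load_class_library


@pytest.fixture(scope="session")
def library():
    return load_class_library()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
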