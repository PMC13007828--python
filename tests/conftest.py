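import numpy as np
import pytest

from neohfa.filters import design_ripple_fir

FS = 1024.0


@pytest.fixture(scope="session")
def fs() -> float:
    return FS


@pytest.fixture(scope="session")
def ripple_taps() -> np.ndarray:
    return design_ripple_fir(FS)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
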