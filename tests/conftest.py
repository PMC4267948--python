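import numpy as np
import pytest

from phyloerr.substmodel import build_model


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def k2p():
    """The study's substitution model: K2P with transition/transversion ratio 2."""
    return build_model(2.0)
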