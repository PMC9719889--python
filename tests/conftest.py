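import numpy as np
import pytest

from helpers import make_evaluation


@pytest.fixture
def make_eval():
    """Factory for constraint evaluations with explicit boolean vectors."""
    return make_evaluation


@pytest.fixture
def rng():
    return np.random.default_rng(20260917)
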