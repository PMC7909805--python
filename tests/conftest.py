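import numpy as np
import pytest

from mahds.simulate import toy_grammar_set


@pytest.fixture(scope="session")
def toy_set():
    """The 12-sequence dinucleotide-grammar toy alignment."""
    return toy_grammar_set()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
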