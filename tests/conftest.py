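import numpy as np
import pytest


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_founders():
    """A small drifted founder population shared across read-only tests."""
    from pelselect import make_founders

    return make_founders(n_lines=300, n_loci=500, allele_freq=0.5,
                         n_generations=40, seed=123)
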