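import numpy as np
import pytest

import pelagiscope as pg


@pytest.fixture(scope="session")
def reference():
    """A Skadi-like reference: 35,392 bp at 31.5% G+C."""
    return pg.simulate_genome(35392, 0.315, seed=11, genome_id="phageA")


@pytest.fixture(scope="session")
def small_genome():
    return pg.simulate_genome(2000, 0.40, seed=13, genome_id="mini")


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
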