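import numpy as np
import pytest

import epismc as e


@pytest.fixture(scope="session")
def constant_data():
    """Two-marker constant-N data, small scale (shared across tests)."""
    return e.generate_fixture("constant", seed=11, sequence_length=400_000)


@pytest.fixture(scope="session")
def methylome_data():
    """Site-epimutation-only methylome under the severe-bottleneck scenario."""
    return e.generate_fixture("methylome_fig5", seed=7, sequence_length=400_000)


@pytest.fixture(scope="session")
def methylome_region_data():
    """Methylome with both site- and region-level epimutation."""
    return e.generate_fixture("methylome_both", seed=7, sequence_length=400_000)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
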