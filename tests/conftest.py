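import numpy as np
import pytest

from fourfold import from_counts, titanic_fixture


@pytest.fixture
def mammography():
    """The screening-test table reconstructed for N = 1000 women."""
    return from_counts(8, 95, 2, 895)


@pytest.fixture
def titanic():
    return titanic_fixture()


@pytest.fixture
def random_tables():
    """Seeded stream of frequency tables with all margins nonzero."""

    def make(n_tables: int, seed: int = 20260928, low: int = 1, high: int = 60):
        rng = np.random.default_rng(seed)
        cells = rng.integers(low, high, size=(n_tables, 4))
        return [from_counts(*(int(v) for v in row)) for row in cells]

    return make
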