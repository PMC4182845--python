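import numpy as np
import pytest

from mulchres import GrayHistogram, table1_frame


@pytest.fixture(scope="session")
def table1():
    return table1_frame()


def random_histogram(rng: np.random.Generator, n_bins: int = 256) -> GrayHistogram:
    """A random sparse histogram with mass in at least two bins."""
    k = rng.integers(2, 12)
    bins = rng.choice(n_bins, size=k, replace=False)
    counts = np.zeros(n_bins, dtype=np.int64)
    counts[bins] = rng.integers(1, 1000, size=k)
    return GrayHistogram(counts)


@pytest.fixture
def rng():
    return np.random.default_rng(20090817)
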