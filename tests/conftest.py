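import numpy as np
import pytest

from hicsv import ContactMatrix, bin_genome


@pytest.fixture
def toy_bins():
    """Three small chromosomes at 50 kb resolution."""
    return bin_genome({"chr1": 200_000, "chr2": 150_000, "chr3": 100_000},
                      50_000)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_matrix(bins, rng, max_count=20) -> ContactMatrix:
    """Random symmetric count matrix over all blocks of ``bins``."""
    blocks = {}
    cs = bins.chroms
    for i, ca in enumerate(cs):
        na = bins.n_bins(ca)
        a = rng.integers(0, max_count, size=(na, na)).astype(float)
        blocks[(ca, ca)] = np.triu(a) + np.triu(a, 1).T
        for cb in cs[i + 1:]:
            blocks[(ca, cb)] = rng.integers(
                0, max_count, size=(na, bins.n_bins(cb))).astype(float)
    return ContactMatrix(bins, blocks, kind="counts")
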