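import numpy as np
import pytest

from dmbtkit.selscan import HaplotypeMatrix


@pytest.fixture
def ladder_matrix() -> HaplotypeMatrix:
    """Four haplotypes forming a ladder: 000, 100, 110, 111."""
    alleles = np.array([[0, 0, 0],
                        [1, 0, 0],
                        [1, 1, 0],
                        [1, 1, 1]], dtype=np.uint8)
    return HaplotypeMatrix("chrT", [101, 202, 303], alleles)


@pytest.fixture
def two_block_matrix() -> HaplotypeMatrix:
    """Two groups of identical haplotypes differing at 5 sites."""
    block = np.zeros((6, 5), dtype=np.uint8)
    block[3:, :] = 1
    return HaplotypeMatrix("chrT", [10, 20, 30, 40, 50], block)
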