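import numpy as np
import pytest

from balpoly.windows import HaplotypeWindow


@pytest.fixture
def worked_window():
    """4 haplotypes, 100 covered sites, two variant sites with derived
    counts 2 and 1 — the hand-countable diversity example."""
    alleles = np.zeros((4, 2), dtype=np.int8)
    alleles[:2, 0] = 1
    alleles[0, 1] = 1
    return HaplotypeWindow(
        alleles=alleles,
        positions=np.array([10, 20]),
        window_start=1,
        window_length=100,
        n_monomorphic_covered=98,
    )


def make_window(alleles, positions=None, length=100, n_mono=0):
    alleles = np.asarray(alleles, dtype=np.int8)
    if positions is None:
        positions = np.arange(1, alleles.shape[1] + 1)
    return HaplotypeWindow(
        alleles=alleles,
        positions=positions,
        window_start=1,
        window_length=length,
        n_monomorphic_covered=n_mono,
    )
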