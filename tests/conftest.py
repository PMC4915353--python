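import numpy as np
import pytest

from demoskew.population import PopulationState, SampleAlignment


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_population(N, L, rng=None, ancestral=None):
    """Monomorphic population with a fixed (all-A) ancestral by default."""
    if ancestral is None:
        ancestral = np.zeros(L, dtype=np.uint8)
    return PopulationState(N, L, ancestral=ancestral)


def alignment_from_derived_counts(n, L, derived_counts, anc_allele=0,
                                  derived_allele=1):
    """Alignment where site j has its derived allele in the first
    derived_counts[j] sequences; remaining sites are ancestral."""
    seqs = np.full((n, L), anc_allele, dtype=np.uint8)
    for j, c in enumerate(derived_counts):
        seqs[:c, j] = derived_allele
    anc = np.full(L, anc_allele, dtype=np.uint8)
    return SampleAlignment(seqs, anc)
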