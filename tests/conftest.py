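import numpy as np
import pytest

from identikin.kinship import Pedigree
from identikin.synthdata import (
    balding_nichols_freqs,
    sample_ancestral_freqs,
    simulate_genotypes,
)


@pytest.fixture(scope="session")
def three_pop_freqs():
    """Balding-Nichols frequencies for three diverged populations (fst=0.1)."""
    anc = sample_ancestral_freqs(5000, seed=101)
    return balding_nichols_freqs(anc, 0.1, 3, seed=102)


@pytest.fixture(scope="session")
def chain_pedigree():
    """Four-generation chain A -> B -> C -> D with outbred founder mates."""
    return Pedigree(
        [
            ("A", None, None, "M"),
            ("Am", None, None, "F"),
            ("B", "A", "Am", "F"),
            ("Bm", None, None, "M"),
            ("C", "Bm", "B", "F"),
            ("Cm", None, None, "M"),
            ("D", "Cm", "C", "M"),
            ("U", None, None, "F"),
        ]
    )


@pytest.fixture
def small_gm():
    """Tiny deterministic genotype matrix for filter/prune unit tests."""
    rng = np.random.default_rng(7)
    Q = np.ones((6, 1))
    anc = sample_ancestral_freqs(40, seed=8)
    F = balding_nichols_freqs(anc, 0.2, 1, seed=9)
    return simulate_genotypes(F, Q, seed=10)
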