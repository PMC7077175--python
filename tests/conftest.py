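import numpy as np
import pytest

from _factories import toy_freqs, toy_structure
from stratpca import egrm_elements, genotype_moments


@pytest.fixture
def toy():
    """The 2-population worked example: N = (2, 2), one SNP, f = (0.2, 0.8).

    Under mixture moments mu = 1, sigma^2 = 0.68, giving z^k = 1,
    z^kk = 9/17 and z^12 = -9/17; structural eigenvalues 44/17 and 8/17.
    """
    structure = toy_structure()
    freqs = toy_freqs()
    norm = genotype_moments(structure, freqs, mode="mixture")
    summary = egrm_elements(structure, freqs, norm)
    return structure, freqs, norm, summary


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
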