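"""Shared generators for randomized population/frequency instances."""

from __future__ import annotations

import numpy as np

from stratpca import (
    AlleleFrequencyTable,
    PopulationStructure,
    egrm_elements,
    genotype_moments,
)


def toy_structure() -> PopulationStructure:
    return PopulationStructure(labels=["A", "B"], sizes=np.array([2, 2]))


def toy_freqs() -> AlleleFrequencyTable:
    return AlleleFrequencyTable(snp_ids=["rs1"], freqs=np.array([[0.2], [0.8]]))


def random_instance(
    rng: np.random.Generator,
    k_range=(1, 5),
    size_range=(1, 50),
    m_range=(1, 8),
    modes=("mixture", "total_binomial"),
):
    """A random (structure, frequency table, norm params, block summary).

    Frequencies are drawn in [0.05, 0.95] so every SNP is polymorphic in
    the total population under every moment convention.
    """
    k = int(rng.integers(k_range[0], k_range[1] + 1))
    sizes = rng.integers(size_range[0], size_range[1] + 1, size=k)
    m = int(rng.integers(m_range[0], m_range[1] + 1))
    freqs = rng.uniform(0.05, 0.95, size=(k, m))
    structure = PopulationStructure(labels=[f"P{i + 1}" for i in range(k)], sizes=sizes)
    table = AlleleFrequencyTable(snp_ids=[f"s{j + 1}" for j in range(m)], freqs=freqs)
    mode = modes[int(rng.integers(len(modes)))]
    norm = genotype_moments(structure, table, mode=mode)
    summary = egrm_elements(structure, table, norm)
    return structure, table, norm, summary
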