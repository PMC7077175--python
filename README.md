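# stratpca

Expected genetic relationship matrices (EGRMs) and PCA-based
population-divergence statistics for stratified samples.

## The problem

PCA of a genetic relationship matrix (GRM) is the standard way to detect
and correct population stratification in genome-wide association studies.
How well it works depends on the allele frequencies of the markers used:
with rare variants the population signal carried by the top principal
components collapses. `stratpca` makes this quantitative. It is aimed at
statistical geneticists who want to predict, from allele frequencies alone,
how much population structure a PCA will recover — before computing a
single genotype-based GRM.

## The model

Samples come from `K` populations of sizes `N_1..N_K`; within population
`k` the coded-allele count of SNP `m` is Binomial(2, `f_km`)
(Hardy–Weinberg equilibrium). The GRM is `Z = (1/M) Y Yᵀ` with
standardized genotypes `Y(n,m) = (X(n,m) − μ_m)/σ_m`. Its expectation, the
EGRM, is block-structured and fully determined by `{N_k}` and `{f_km}`:
diagonal `z^k`, within-block `z^kk`, cross-block `z^kl`. Exactly `K`
eigenvalues of the EGRM (the eigenvalues of a `K×K` reduced matrix) carry
all inter-population variance; the remaining `N−K` equal `z^k − z^kk` with
multiplicity `N_k − 1`. Divergence is summarized by

* `σ_B² = Σ N_k z^kk`, `σ_W² = Σ (z^k − z^kk)`
* `F_PC = σ_B²/σ_W²` and `F_PC* = σ_B²/(σ_B²+σ_W²)`
* `d² = Σ λ_k − (1/N) Σ N_k (z^k − z^kk)`, the sum of squared distances of
  samples from the grand center in `√λ`-scaled structural coordinates.

All of these shrink as the coded-allele frequencies shrink — the precise
sense in which PCA of population stratification performs worse with rare
variants.

## Worked example

Two populations of two samples, one SNP with frequencies 0.2 and 0.8:

```python
import numpy as np
from stratpca import (PopulationStructure, AlleleFrequencyTable,
                      divergence_report)

structure = PopulationStructure(["A", "B"], np.array([2, 2]))
freqs = AlleleFrequencyTable(["rs1"], np.array([[0.2], [0.8]]))
rep = divergence_report(structure, freqs, norm_mode="mixture")
print(f"F_PC={rep.f_pc:.4f}  F_PC*={rep.f_pc_star:.4f}  d2={rep.d2:.4f}")
```

prints

```
F_PC=2.2500  F_PC*=0.6923  d2=2.5882
```

Under exact mixture moments (μ = 1, σ² = 0.68) the EGRM elements are
`z^k = 1`, `z^kk = 9/17`, `z^12 = −9/17`; the two structural eigenvalues
are 44/17 ≈ 2.588 and 8/17 ≈ 0.471. Inter-population variance
σ_B² = 36/17 is 2.25 times the intra component σ_W² = 16/17, and d² = 44/17
because with equal intra variance all population separation sits in the
largest PC.

The same pipeline from the shell:

```bash
stratpca simulate --pop EUR:500 --pop EAS:500 --snps 2000 --maf-bin 1 \
    --divergence 0.1 --seed 7 --out-prefix panel
stratpca divergence --freqs panel.freqs.tsv --out report.tsv
stratpca grm --genotypes panel.genotypes.tsv --labels panel.labels.tsv --out grm.tsv
stratpca pca --matrix grm.tsv --labels panel.labels.tsv --topk 5 --scaled \
    --out-prefix pcs
```

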