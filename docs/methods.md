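# Methods

## Model and assumptions

The package analyzes PCA of population stratification under an explicit
sampling model: `N` unrelated individuals drawn from `K` populations of
sizes `N_1..N_K`, genotyped at `M` biallelic SNPs whose coded-allele
frequency in population `k` is `f_km`, with Hardy–Weinberg equilibrium
within each population and no linkage disequilibrium between sites.
Genotypes are standardized as `Y = (X − μ_m)/σ_m` and the GRM is
`Z = (1/M) Y Yᵀ`. Because each SNP contributes additively to `Z`, the
expectation of `Z` (the EGRM) is a block matrix determined entirely by
`{N_k}` and `{f_km}`; the theory is asymptotic in `M` (law of large
numbers over SNPs), and LD slows but does not break the convergence.

## Moment conventions

The standardization constants `(μ_m, σ_m)` admit several conventions, all
exposed as named modes because results other than single-SNP `F_PC` depend
on the choice:

| mode | σ_m² | use |
|---|---|---|
| `mixture` | exact variance of the binomial mixture | theoretical reference |
| `total_binomial` | `2 f_m (1 − f_m)` at the pooled frequency | default for divergence reports |
| `gcta` | `2 f̂_m (1 − f̂_m)` | sample-estimated analogue |
| `eigensoft` | `f̂_m (1 − f̂_m)` | EIGENSOFT-style normalization |
| `sample` | observed column SD (ddof = 1) | fully empirical |

The mixture variance sums its between-population term over unordered
population pairs; this is forced by the law of total variance and is
verified in the tests against brute-force enumeration of the mixture
distribution over genotype values {0, 1, 2}. `total_binomial` is the
default for divergence reports because it is the convention under which
theoretical and tool-computed empirical block values are directly
comparable. Note that with `eigensoft` normalization the EGRM diagonal is
near 2, not 1 — σ² is half the binomial variance; the package does not
rescale and simply exposes every mode.

Monomorphic-in-total-population SNPs have σ_m = 0 and are a hard error in
strict mode; pipeline callers (`normalize_genotypes(strict=False)`, the
CLI default for `grm`, estimated-mode experiments) drop such columns with
a logged warning and report drop counts.

## Eigenstructure

The EGRM spectrum is computed exactly rather than numerically thresholded:
population `k` contributes `N_k − 1` eigenvalues equal to `z^k − z^kk`,
and the `K` structural eigenvalues are those of the reduced matrix
`B_kk = (z^k − z^kk) + N_k z^kk`, `B_kl = √(N_k N_l) z^kl`, whose
eigenvectors map to block-constant length-`N` eigenvectors with value
`u_k/√N_k` in block `k`. This reduced-matrix route separates structural
from intra eigenvalues even when they are numerically degenerate (the
worked example has λ₂ = z¹ − z¹¹ exactly), which magnitude-sorting of the
full spectrum cannot do. For two populations the closed-form pair
λ₁, λ₂ with discriminant
`a = [(z¹−z¹¹) − (z²−z²²) + N₁z¹¹ − N₂z²²]² + 4N₁N₂(z¹²)²` is also
provided and tested against the reduced matrix to 1e−10.

Eigenvector signs follow a deterministic convention (largest-magnitude
entry positive, ties broken by lowest index) so file outputs are
reproducible. Within numerically repeated eigenvalues the reported basis
is whatever the decomposition returns after sign fixing; tests that touch
degenerate spectra compare eigenvalue multisets or invariant quantities,
not individual vectors.

Variance explained is reported as λ_i over the full trace. For EGRMs the
structural eigenvalue sum over the full trace is also available via the
structural spectrum (`all_eigenvalues()`), since both denominators are of
interest when comparing GRM-PCA and EGRM-PCA percentages.

## Representative points and d²

Exact population centers exist only for theoretical EGRMs: the center of
population `k` in structural dimension `j` is `√λ_j · u_jk/√N_k`.
`representative_points` therefore takes the structural spectrum and
refuses numeric `EigenResult` input — for an observed GRM the eigenvectors
are only approximately block-constant, and in degenerate eigenspaces the
numeric basis mixes structural and intra directions, so an approximate
variant (`approximate_representative_points`) averages scaled sample
coordinates within populations instead. The distance statistic
`d² = Σλ_k − (1/N)ΣN_k(z^k − z^kk)` is checked against its coordinate-space
definition (sum of squared sample deviations from the grand center).

A subtlety worth documenting: `d²` does not vanish for identical
populations. With `z^kk = z^kl = 0` the `K` "structural" eigenvalues are
pure intra variance and `d² = σ_W²(1 − 1/K)` for equal sizes — the
representative points are scattered by intra variance even without any
true separation. `d²` is therefore meaningful as a comparative measure
across frequency panels (it is monotone under proportional frequency
shrinkage), not as an absolute zero-calibrated distance. The empirical
variant `pop_distance_d2_empirical` (top-K GRM eigenvalues minus the
grand-mean quadratic form) is labeled approximate.

## Synthetic data

`simulate_genotypes` draws `X(n,m) ~ Binomial(2, f_km)` independently —
exactly the model above, so passing convergence tests demonstrate
correctness of the formulas, not robustness to LD, relatedness,
genotyping error or missingness, none of which the generator emulates.

`draw_frequency_panel` stands in for sampling real SNPs by MAF bin. It
draws a pooled target frequency uniformly in the requested MAF interval
(bins 1–6: (0.4,0.5], (0.3,0.4], (0.2,0.3], (0.1,0.2], (0.01,0.1],
(0.0001,0.01], with the coded allele taken as the minor one) and then
per-population frequencies from a Balding–Nichols Beta distribution with
mean `f` and variance `F·f(1−f)`. The `divergence` parameter is the
Balding–Nichols `F`, i.e. approximately the single-SNP F_ST of the drawn
panel; the default 0.1 is a continental-human scale of differentiation.
Draws are rejection-sampled until the realized size-weighted pooled MAF
lies in the interval and the SNP is polymorphic in the pooled sample;
individual populations may be monomorphic, as real rare variants are.

Randomness: one integer master seed everywhere; replicate experiments
spawn per-replicate substreams with `numpy.random.SeedSequence(seed)` so
results are reproducible regardless of execution order.

## Replicate experiment

`convergence_experiment` compares theoretical `z^k`, `z^kk` with
block-averaged GRM values over replicates, in two modes: `known` uses the
chosen moment convention at the true frequencies; `estimated` re-estimates
`2f̂(1−f̂)` moments per replicate from the simulated genotypes, isolating
the cost of not knowing `μ_m, σ_m`. For common SNPs the two modes agree
with theory to Monte-Carlo noise; for rare SNPs (f ≈ 0.005) the estimated
mode shows a persistent bias in `z^kk` that does not shrink with more
replicates, visible already at a few hundred replicates. The diagonal
`z^k` of single rare SNPs is heavy-tailed (standardized genotypes take
values near 20), so its replicate mean is noise-dominated at moderate
replicate counts and is not used for the known-vs-estimated comparison.

## Problem sizes and numerics

The test suite exercises the exact theorems on hundreds of randomized
instances with `K ≤ 5`, `N_k ≤ 50` (exact checks at 1e−8/1e−10), and the
Monte-Carlo checks at `N = 400–2500` samples and `M` up to 1e5 SNPs —
sizes at which the asymptotic identities are already sharp while the whole
suite runs in well under five minutes. Matrices are dense float64
throughout; symmetry is enforced by averaging `Z` with its transpose
before `eigh`. Eigen-decompositions use LAPACK via `numpy.linalg.eigh`.
Tiny negative structural eigenvalues arising from round-off are clipped at
zero before taking square roots for scaled coordinates.

## Known limitations

* No missing-genotype handling in core operations (the model assumes
  complete data; imputation would silently change the GRM definition).
* No LD-aware simulation or coalescent demography; the generator is
  site-independent by design.
* `F_PC` is invariant to the σ_m convention only for `M = 1`; multi-SNP
  `F_PC` aggregates pooled variance components and depends on the chosen
  mode, so reports always record `norm_mode`.
* Biobank-scale `N` is out of scope: the dense `N×N` matrix and full
  eigendecomposition are materialized when requested.
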