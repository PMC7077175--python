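"""Core domain types, genotype moments and MAF binning.

The model underlying this package: genotypes of ``M`` biallelic SNPs are
observed on ``N`` individuals sampled from ``K`` populations of sizes
``N_1..N_K``.  Within population ``k`` the coded-allele count of SNP ``m``
is Binomial(2, f_km) (Hardy-Weinberg equilibrium within each population),
so the total-population genotype at a SNP follows a mixture of binomials
with mixing weights ``N_k / N``.  The genotypic mean and variance of that
mixture,

    mu_m     = 2 * sum_k N_k f_km / N
    sigma_m2 = 2 * sum_k (N_k/N) f_km (1 - f_km)
               + 4 * sum_{k<l} (N_k N_l / N^2) (f_km - f_lm)^2,

are the quantities used to center and standardize genotypes before
computing relationship matrices.  Alternative standardization conventions
used by common PCA tools are exposed as named modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np

__all__ = [
    "MonomorphicSNPError",
    "StructureError",
    "PopulationStructure",
    "AlleleFrequencyTable",
    "GenotypeMatrix",
    "NormalizationParams",
    "MOMENT_MODES",
    "MAF_BINS",
    "total_allele_frequency",
    "genotype_moments",
    "assign_maf_bin",
    "maf_bin_range",
    "mixture_moments_bruteforce",
]

#: standardization conventions for (mu_m, sigma_m)
MOMENT_MODES = ("mixture", "total_binomial", "eigensoft", "gcta", "sample")

#: MAF bins, numbered 1..6, as half-open intervals (lo, hi] on the
#: total-population minor allele frequency.  A MAF at or below the lowest
#: edge (1e-4) falls in no bin.
MAF_BINS = {
    1: (0.4, 0.5),
    2: (0.3, 0.4),
    3: (0.2, 0.3),
    4: (0.1, 0.2),
    5: (0.01, 0.1),
    6: (0.0001, 0.01),
}


class StructureError(ValueError):
    """Dimension or consistency error between structure and data objects."""


class MonomorphicSNPError(ValueError):
    """A SNP is monomorphic in the total population (sigma_m = 0)."""


@dataclass
class PopulationStructure:
    """K populations with sizes N_k; samples ordered by population block.

    Parameters
    ----------
    labels
        K population names, unique.
    sizes
        K positive integer sample counts.
    """

    labels: list[str]
    sizes: np.ndarray

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.sizes = np.asarray(self.sizes, dtype=np.int64)
        if self.sizes.ndim != 1 or self.sizes.size < 1:
            raise StructureError("need at least one population")
        if len(self.labels) != self.sizes.size:
            raise StructureError("labels and sizes differ in length")
        if len(set(self.labels)) != len(self.labels):
            raise StructureError("population labels must be unique")
        if np.any(self.sizes < 1):
            raise StructureError("population sizes must be positive")

    @property
    def n_populations(self) -> int:
        return len(self.labels)

    @property
    def n_samples(self) -> int:
        return int(self.sizes.sum())

    @property
    def weights(self) -> np.ndarray:
        """Population proportions N_k / N."""
        return self.sizes / self.n_samples

    @property
    def membership(self) -> np.ndarray:
        """Length-N vector of population indices, block-contiguous."""
        return np.repeat(np.arange(self.n_populations), self.sizes)

    def block_slices(self) -> list[slice]:
        """Row/column slice of each population block in sample order."""
        bounds = np.concatenate([[0], np.cumsum(self.sizes)])
        return [slice(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]

    def default_sample_ids(self) -> list[str]:
        return [
            f"{lab}_{i + 1}"
            for lab, n in zip(self.labels, self.sizes)
            for i in range(int(n))
        ]


@dataclass
class AlleleFrequencyTable:
    """Coded-allele frequencies f_km, one row per population, one column per SNP."""

    snp_ids: list[str]
    freqs: np.ndarray  # shape (K, M)

    def __post_init__(self) -> None:
        self.snp_ids = list(self.snp_ids)
        self.freqs = np.atleast_2d(np.asarray(self.freqs, dtype=float))
        if self.freqs.shape[1] != len(self.snp_ids):
            raise StructureError("snp_ids and frequency columns differ in length")
        if self.freqs.shape[1] < 1:
            raise StructureError("need at least one SNP")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise StructureError("duplicate SNP identifiers")
        if np.any(self.freqs < 0) or np.any(self.freqs > 1) or not np.all(
            np.isfinite(self.freqs)
        ):
            raise StructureError("allele frequencies must lie in [0, 1]")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_populations(self) -> int:
        return self.freqs.shape[0]


@dataclass
class GenotypeMatrix:
    """N x M coded-allele counts in {0, 1, 2}; missing values are rejected."""

    values: np.ndarray
    sample_ids: list[str]
    snp_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise StructureError("genotype matrix must be 2-dimensional")
        if not np.issubdtype(self.values.dtype, np.integer):
            asint = self.values.astype(np.int64, copy=True)
            if not np.array_equal(
                asint, np.asarray(self.values, dtype=float), equal_nan=False
            ):
                raise StructureError("genotype values must be integers")
            self.values = asint
        if self.values.size and not np.isin(self.values, (0, 1, 2)).all():
            raise StructureError("genotype values must be 0, 1 or 2 (no missing)")
        if len(self.sample_ids) != self.values.shape[0]:
            raise StructureError("sample_ids length mismatch")
        if len(self.snp_ids) != self.values.shape[1]:
            raise StructureError("snp_ids length mismatch")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]


@dataclass
class NormalizationParams:
    """Per-SNP genotypic mean mu_m and standard deviation sigma_m.

    ``mode`` records the convention: ``mixture`` (exact mixture-of-binomials
    moments), ``total_binomial`` (sigma^2 = 2 f_m (1 - f_m) at the pooled
    frequency), ``eigensoft`` (sigma^2 = f_m (1 - f_m)), ``gcta``
    (sigma^2 = 2 f_m (1 - f_m)) or ``sample`` (observed column moments).
    """

    mu: np.ndarray
    sigma: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.mu.shape != self.sigma.shape or self.mu.ndim != 1:
            raise StructureError("mu and sigma must be 1-d of equal length")
        if self.mode not in MOMENT_MODES:
            raise ValueError(f"unknown moment mode {self.mode!r}")
        if np.any(self.mu < 0) or np.any(self.mu > 2):
            raise StructureError("mu must lie in [0, 2]")

    @property
    def total_frequency(self) -> np.ndarray:
        """Pooled coded-allele frequency f_m = mu_m / 2."""
        return self.mu / 2.0


def _check_pair(structure: PopulationStructure, freqs: AlleleFrequencyTable) -> None:
    if structure.n_populations != freqs.n_populations:
        raise StructureError(
            f"frequency table has {freqs.n_populations} populations, "
            f"structure has {structure.n_populations}"
        )


def total_allele_frequency(
    structure: PopulationStructure, freqs: AlleleFrequencyTable
) -> np.ndarray:
    """Pooled coded-allele frequency f_m = sum_k N_k f_km / N, per SNP."""
    _check_pair(structure, freqs)
    return structure.weights @ freqs.freqs


def genotype_moments(
    structure: PopulationStructure,
    freqs: AlleleFrequencyTable,
    mode: str = "mixture",
) -> NormalizationParams:
    """Genotypic mean and standard deviation per SNP under a named convention.

    ``mixture`` gives the exact variance of the binomial mixture (the
    between-population term runs over unordered population pairs, which is
    what the law of total variance requires).  ``total_binomial``/``gcta``
    use 2 f_m (1 - f_m) at the pooled frequency; ``eigensoft`` uses
    f_m (1 - f_m).

    Raises
    ------
    MonomorphicSNPError
        If any SNP has sigma_m = 0 (monomorphic in the total population).
    """
    _check_pair(structure, freqs)
    if mode == "sample":
        raise ValueError("mode='sample' requires genotypes; see estimate_norm_params")
    if mode not in MOMENT_MODES:
        raise ValueError(f"unknown moment mode {mode!r}")

    w = structure.weights
    f = freqs.freqs
    f_total = w @ f
    mu = 2.0 * f_total
    if mode == "mixture":
        within = 2.0 * (w @ (f * (1.0 - f)))
        # sum_{k<l} w_k w_l (f_k - f_l)^2 == E_w[f^2] - (E_w[f])^2
        between = 4.0 * (w @ f**2 - f_total**2)
        sigma2 = within + between
    elif mode in ("total_binomial", "gcta"):
        sigma2 = 2.0 * f_total * (1.0 - f_total)
    else:  # eigensoft
        sigma2 = f_total * (1.0 - f_total)

    bad = np.flatnonzero(sigma2 <= 0)
    if bad.size:
        names = ", ".join(freqs.snp_ids[i] for i in bad[:5])
        raise MonomorphicSNPError(
            f"{bad.size} SNP(s) monomorphic in the total population: {names}"
        )
    return NormalizationParams(mu=mu, sigma=np.sqrt(sigma2), mode=mode)


def assign_maf_bin(f_total: float) -> int | None:
    """MAF bin number (1..6) for a total-population frequency, or None.

    MAF = min(f, 1-f); bins are half-open intervals (lo, hi] per
    :data:`MAF_BINS`.  MAF <= 1e-4 belongs to no bin.
    """
    if not 0.0 <= f_total <= 1.0:
        raise ValueError(f"frequency {f_total} outside [0, 1]")
    maf = min(f_total, 1.0 - f_total)
    for b, (lo, hi) in MAF_BINS.items():
        if lo < maf <= hi:
            return b
    return None


def maf_bin_range(bin_number: int) -> tuple[float, float]:
    """The (lo, hi] MAF interval of a bin number."""
    try:
        return MAF_BINS[int(bin_number)]
    except KeyError:
        raise ValueError(f"no such MAF bin: {bin_number}") from None


def mixture_moments_bruteforce(
    sizes: np.ndarray, freqs_one_snp: np.ndarray
) -> tuple[float, float]:
    """Exact mean/variance of one SNP's genotype mixture by enumeration.

    Independent oracle for :func:`genotype_moments` in mixture mode:
    enumerates P(X = x), x in {0, 1, 2}, under the binomial mixture
    sum_k (N_k/N) Binomial(2, f_k).
    """
    sizes = np.asarray(sizes, dtype=float)
    w = sizes / sizes.sum()
    fk = np.asarray(freqs_one_snp, dtype=float)
    px = np.zeros(3)
    for x in range(3):
        px[x] = float(
            np.sum(w * comb(2, x) * fk**x * (1.0 - fk) ** (2 - x))
        )
    xs = np.arange(3.0)
    mean = float(px @ xs)
    var = float(px @ xs**2 - mean**2)
    return mean, var
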