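"""Empirical genetic relationship matrix from observed genotypes.

Z = (1/M) Y Y^T where Y(n, m) = (X(n, m) - mu_m) / sigma_m.  Moment
parameters either come from known population frequencies
(:func:`stratpca.model.genotype_moments`) or are estimated from the
genotype columns (:func:`estimate_norm_params`), mirroring the
known-vs-estimated comparison the theory is validated against.
"""

from __future__ import annotations

import logging

import numpy as np

from .egrm import EMPIRICAL_GRM, BlockSummary, RelationshipMatrix
from .model import (
    GenotypeMatrix,
    MonomorphicSNPError,
    NormalizationParams,
    PopulationStructure,
    StructureError,
)

__all__ = [
    "normalize_genotypes",
    "compute_grm",
    "estimate_norm_params",
    "block_summaries",
]

logger = logging.getLogger(__name__)


def estimate_norm_params(
    genotypes: GenotypeMatrix, mode: str = "gcta", *, strict: bool = True
) -> NormalizationParams:
    """Estimate mu_m and sigma_m from genotype columns.

    ``gcta``/``total_binomial``: sigma = sqrt(2 f (1 - f)) at the sample
    frequency f = column mean / 2; ``eigensoft``: sqrt(f (1 - f));
    ``sample``: the observed column standard deviation (ddof=1).

    With ``strict=True`` monomorphic columns (sigma = 0) raise; otherwise
    they are kept with sigma 0 and dropped later by
    :func:`normalize_genotypes`.
    """
    if genotypes.n_samples < 1 or genotypes.n_snps < 1:
        raise StructureError("empty genotype matrix")
    x = genotypes.values.astype(float)
    fhat = x.mean(axis=0) / 2.0
    mu = 2.0 * fhat
    if mode in ("gcta", "total_binomial"):
        sigma = np.sqrt(2.0 * fhat * (1.0 - fhat))
        mode = "gcta"
    elif mode == "eigensoft":
        sigma = np.sqrt(fhat * (1.0 - fhat))
    elif mode == "sample":
        if genotypes.n_samples < 2:
            raise StructureError("sample standard deviation needs >= 2 samples")
        sigma = x.std(axis=0, ddof=1)
    elif mode == "mixture":
        raise ValueError(
            "mixture moments require per-population frequencies; see genotype_moments"
        )
    else:
        raise ValueError(f"unknown moment mode {mode!r}")

    if strict:
        bad = np.flatnonzero(sigma <= 0)
        if bad.size:
            names = ", ".join(genotypes.snp_ids[i] for i in bad[:5])
            raise MonomorphicSNPError(
                f"{bad.size} monomorphic SNP(s) in the sample: {names}"
            )
    return NormalizationParams(mu=mu, sigma=sigma, mode=mode)


def normalize_genotypes(
    genotypes: GenotypeMatrix, norm: NormalizationParams, *, strict: bool = True
) -> np.ndarray:
    """Standardize genotypes: Y(n, m) = (X(n, m) - mu_m) / sigma_m.

    Columns with sigma_m = 0 raise :class:`MonomorphicSNPError` in strict
    mode; with ``strict=False`` they are dropped with a logged warning and
    the returned matrix has fewer columns.
    """
    if norm.mu.size != genotypes.n_snps:
        raise StructureError("normalization parameters do not match SNP count")
    keep = norm.sigma > 0
    if not keep.all():
        dropped = int((~keep).sum())
        if strict:
            bad = np.flatnonzero(~keep)
            names = ", ".join(genotypes.snp_ids[i] for i in bad[:5])
            raise MonomorphicSNPError(
                f"{dropped} monomorphic SNP(s): {names}"
            )
        logger.warning("dropping %d monomorphic SNP column(s)", dropped)
    x = genotypes.values[:, keep].astype(float)
    return (x - norm.mu[keep]) / norm.sigma[keep]


def compute_grm(
    normalized: np.ndarray,
    sample_ids: list[str] | None = None,
    structure: PopulationStructure | None = None,
) -> RelationshipMatrix:
    """Empirical GRM Z = (1/M) Y Y^T from standardized genotypes."""
    y = np.asarray(normalized, dtype=float)
    if y.ndim != 2 or y.shape[1] < 1:
        raise StructureError("normalized genotype matrix is empty")
    z = y @ y.T / y.shape[1]
    z = (z + z.T) / 2.0  # exact symmetry despite fp round-off
    return RelationshipMatrix(
        values=z, kind=EMPIRICAL_GRM, structure=structure, sample_ids=sample_ids
    )


def block_summaries(
    matrix: RelationshipMatrix, structure: PopulationStructure
) -> BlockSummary:
    """Block-average a relationship matrix into z^k, z^kk, z^kl estimates.

    z^k is the mean diagonal in block k; z^kk the mean of the
    N_k(N_k-1)/2 within-block off-diagonal pairs (NaN when N_k = 1);
    z^kl the mean of the N_k N_l cross-block entries.
    """
    if structure.n_samples != matrix.n_samples:
        raise StructureError("matrix dimension does not match structure")
    z = matrix.values
    slices = structure.block_slices()
    k = structure.n_populations
    zk = np.empty(k)
    zkk = np.empty(k)
    zkl = np.empty((k, k))
    for i, si in enumerate(slices):
        block = z[si, si]
        nk = block.shape[0]
        zk[i] = block.diagonal().mean()
        if nk > 1:
            zkk[i] = (block.sum() - block.diagonal().sum()) / (nk * (nk - 1))
        else:
            zkk[i] = np.nan
        for j, sj in enumerate(slices):
            if j > i:
                zkl[i, j] = zkl[j, i] = z[si, sj].mean()
    np.fill_diagonal(zkl, zkk)
    return BlockSummary(zk=zk, zkk=zkk, zkl=zkl)
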