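"""Expected genetic relationship matrix (EGRM) construction.

The expectation of the standardized-genotype relationship matrix is fully
determined by population sizes and per-population allele frequencies.  It
is block-structured: within population ``k`` the diagonal value is the
genotypic variance

    z^k  = (1/M) sum_m [2 f_km (1 - f_km) + (2 f_km - mu_m)^2] / sigma_m^2,

the within-population covariance is

    z^kk = (1/M) sum_m (2 f_km - mu_m)^2 / sigma_m^2,

and the covariance between populations ``k`` and ``l`` is

    z^kl = (1/M) sum_m (2 f_km - mu_m)(2 f_lm - mu_m) / sigma_m^2.

These 2K + K(K-1)/2 numbers (a :class:`BlockSummary`) are the canonical
intermediate; the dense N x N matrix is materialized only on demand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    AlleleFrequencyTable,
    NormalizationParams,
    PopulationStructure,
    StructureError,
    _check_pair,
)

__all__ = ["BlockSummary", "RelationshipMatrix", "egrm_elements", "assemble_egrm"]

EMPIRICAL_GRM = "empirical-GRM"
THEORETICAL_EGRM = "theoretical-EGRM"


@dataclass
class BlockSummary:
    """Block structure of a GRM/EGRM: z^k, z^kk and the symmetric z^kl matrix.

    ``zkk`` entries may be NaN for empirical summaries of size-1 populations
    (no within-population pair exists).  The diagonal of ``zkl`` is set to
    ``zkk`` for convenience.
    """

    zk: np.ndarray  # (K,)
    zkk: np.ndarray  # (K,)
    zkl: np.ndarray  # (K, K) symmetric

    def __post_init__(self) -> None:
        self.zk = np.asarray(self.zk, dtype=float)
        self.zkk = np.asarray(self.zkk, dtype=float)
        self.zkl = np.asarray(self.zkl, dtype=float)
        k = self.zk.size
        if self.zkk.shape != (k,) or self.zkl.shape != (k, k):
            raise StructureError("block summary dimensions inconsistent")
        if not np.allclose(self.zkl, self.zkl.T, equal_nan=True):
            raise StructureError("cross-population covariance matrix must be symmetric")

    @property
    def n_populations(self) -> int:
        return self.zk.size

    @property
    def intra(self) -> np.ndarray:
        """Per-population intra variance z^k - z^kk."""
        return self.zk - self.zkk


@dataclass
class RelationshipMatrix:
    """Dense symmetric N x N relationship matrix with a provenance tag.

    ``kind`` distinguishes matrices computed from observed genotypes
    (``empirical-GRM``) from theoretical expectations (``theoretical-EGRM``)
    so downstream operations can refuse statistically invalid mixes.
    """

    values: np.ndarray
    kind: str
    structure: PopulationStructure | None = None
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape != (n, n):
            raise StructureError("relationship matrix must be square")
        if self.kind not in (EMPIRICAL_GRM, THEORETICAL_EGRM):
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        if self.structure is not None and self.structure.n_samples != n:
            raise StructureError("structure size does not match matrix dimension")
        if self.sample_ids is not None and len(self.sample_ids) != n:
            raise StructureError("sample_ids length does not match matrix dimension")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


def egrm_elements(
    structure: PopulationStructure,
    freqs: AlleleFrequencyTable,
    norm: NormalizationParams,
) -> BlockSummary:
    """Theoretical z^k, z^kk, z^kl from frequencies and moment parameters."""
    _check_pair(structure, freqs)
    if norm.mu.size != freqs.n_snps:
        raise StructureError("normalization parameters do not match SNP count")
    if np.any(norm.sigma <= 0):
        raise StructureError("all sigma_m must be positive")

    f = freqs.freqs
    m = freqs.n_snps
    dev = (2.0 * f - norm.mu) / norm.sigma  # (K, M), centered/scaled deviations
    zkl = dev @ dev.T / m
    zkk = np.diag(zkl).copy()
    zk = zkk + (2.0 * f * (1.0 - f) / norm.sigma**2).mean(axis=1)
    return BlockSummary(zk=zk, zkk=zkk, zkl=zkl)


def assemble_egrm(
    structure: PopulationStructure, summary: BlockSummary
) -> RelationshipMatrix:
    """Materialize the dense N x N EGRM from its block summary."""
    if summary.n_populations != structure.n_populations:
        raise StructureError("summary and structure population counts differ")
    if np.any(~np.isfinite(summary.zkk)) or np.any(~np.isfinite(summary.zk)):
        raise StructureError("cannot assemble an EGRM from missing block values")
    mem = structure.membership
    cross = summary.zkl.copy()
    np.fill_diagonal(cross, summary.zkk)
    values = cross[np.ix_(mem, mem)]
    np.fill_diagonal(values, summary.zk[mem])
    return RelationshipMatrix(
        values=values,
        kind=THEORETICAL_EGRM,
        structure=structure,
        sample_ids=structure.default_sample_ids(),
    )
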