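"""Population divergence statistics from the EGRM eigenstructure.

All inter-population variance in a standardized-genotype PCA is carried by
K eigenvalues.  Their sum splits into

    sigma_B^2 = sum_k N_k z^kk      (inter-population component)
    sigma_W^2 = sum_k (z^k - z^kk)  (intra-population component)

and divergence is measured by F_PC = sigma_B^2 / sigma_W^2, its normalized
version F_PC* = sigma_B^2 / (sigma_B^2 + sigma_W^2) in [0, 1), and the sum
of squared distances of samples from the grand center in
sqrt(lambda)-scaled structural coordinates,

    d^2 = sum_k lambda_k - (1/N) sum_k N_k (z^k - z^kk).

For a single SNP F_PC reduces to a pure frequency statistic and relates to
Wright's fixation index F_ST; both closed forms are provided.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .egrm import BlockSummary, RelationshipMatrix, egrm_elements
from .eigen import structural_spectrum
from .model import (
    AlleleFrequencyTable,
    PopulationStructure,
    StructureError,
    genotype_moments,
)

__all__ = [
    "DivergenceReport",
    "variance_components",
    "fpc",
    "fpc_star",
    "single_snp_fpc",
    "fst",
    "npc_variance_ratio",
    "pop_distance_d2",
    "pop_distance_d2_empirical",
    "divergence_report",
]


@dataclass
class DivergenceReport:
    """Divergence summary of one frequency panel / EGRM."""

    sigma_b2: float
    sigma_w2: float
    f_pc: float
    f_pc_star: float
    d2: float
    k_pcs: int
    n_samples: int
    n_snps: int
    norm_mode: str

    def to_dict(self) -> dict:
        return asdict(self)


def variance_components(
    summary: BlockSummary, structure: PopulationStructure
) -> tuple[float, float]:
    """(sigma_B^2, sigma_W^2) = (sum_k N_k z^kk, sum_k (z^k - z^kk))."""
    if summary.n_populations != structure.n_populations:
        raise StructureError("summary and structure population counts differ")
    sigma_b2 = float(structure.sizes @ summary.zkk)
    sigma_w2 = float(summary.intra.sum())
    return sigma_b2, sigma_w2


def fpc(sigma_b2: float, sigma_w2: float) -> float:
    """F_PC = sigma_B^2 / sigma_W^2."""
    if sigma_w2 <= 0:
        raise ZeroDivisionError("intra-population variance component is zero")
    return sigma_b2 / sigma_w2


def fpc_star(sigma_b2: float, sigma_w2: float) -> float:
    """F_PC* = sigma_B^2 / (sigma_B^2 + sigma_W^2), in [0, 1)."""
    if sigma_b2 + sigma_w2 <= 0:
        raise ZeroDivisionError("total variance of the K structural PCs is zero")
    return sigma_b2 / (sigma_b2 + sigma_w2)


def _single_snp_terms(
    structure: PopulationStructure, f: np.ndarray
) -> tuple[np.ndarray, float]:
    fk = np.asarray(f, dtype=float)
    if fk.shape != (structure.n_populations,):
        raise StructureError("need one frequency per population")
    if np.any(fk < 0) or np.any(fk > 1):
        raise ValueError("frequencies must lie in [0, 1]")
    f_total = float(structure.weights @ fk)
    return fk, f_total


def single_snp_fpc(structure: PopulationStructure, f: np.ndarray) -> float:
    """Single-SNP closed form F_PC = 2 sum N_k (f_k - f)^2 / sum f_k (1 - f_k).

    Independent of the sigma_m convention (sigma cancels when M = 1).
    """
    fk, f_total = _single_snp_terms(structure, f)
    denom = float((fk * (1.0 - fk)).sum())
    if denom <= 0:
        raise ZeroDivisionError("SNP is monomorphic in every population")
    num = float(structure.sizes @ (fk - f_total) ** 2)
    return 2.0 * num / denom


def fst(structure: PopulationStructure, f: np.ndarray) -> float:
    """Wright's fixation index from F_ST/(1-F_ST) = sum N_k (f_k-f)^2 / sum N_k f_k (1-f_k)."""
    fk, f_total = _single_snp_terms(structure, f)
    denom = float(structure.sizes @ (fk * (1.0 - fk)))
    if denom <= 0:
        raise ZeroDivisionError("SNP is monomorphic in every population")
    ratio = float(structure.sizes @ (fk - f_total) ** 2) / denom
    return ratio / (1.0 + ratio)


def npc_variance_ratio(
    summary: BlockSummary, structure: PopulationStructure
) -> float:
    """Inter/intra variance ratio over all N PCs: sigma_B^2 / sum_k N_k (z^k - z^kk).

    For a single SNP this equals 2 F_ST / (1 - F_ST); the K-PC ratio F_PC
    is larger because the N - K pure intra PCs are excluded there.
    """
    denom = float(structure.sizes @ summary.intra)
    if denom <= 0:
        raise ZeroDivisionError("total intra-population variance is zero")
    sigma_b2, _ = variance_components(summary, structure)
    return sigma_b2 / denom


def pop_distance_d2(
    structural_eigenvalues: np.ndarray,
    summary: BlockSummary,
    structure: PopulationStructure,
) -> float:
    """d^2 = sum_k lambda_k - (1/N) sum_k N_k (z^k - z^kk)."""
    lam = np.asarray(structural_eigenvalues, dtype=float)
    if lam.size != structure.n_populations:
        raise StructureError("need exactly K structural eigenvalues")
    mean_intra = float(structure.sizes @ summary.intra) / structure.n_samples
    return float(lam.sum() - mean_intra)


def pop_distance_d2_empirical(
    matrix: RelationshipMatrix, structure: PopulationStructure
) -> float:
    """Approximate d^2 from an observed GRM: top-K eigenvalue sum minus the
    matrix grand mean quadratic form (1/N) 1' Z 1.

    Labeled approximate: the top K numeric eigenpairs of a finite-M GRM only
    estimate the structural eigenpairs of the underlying EGRM.
    """
    if structure.n_samples != matrix.n_samples:
        raise StructureError("matrix dimension does not match structure")
    w = np.linalg.eigvalsh(matrix.values)
    top = np.sort(w)[::-1][: structure.n_populations]
    ones_form = float(matrix.values.sum()) / structure.n_samples
    return float(top.sum() - ones_form)


def divergence_report(
    structure: PopulationStructure,
    freqs: AlleleFrequencyTable,
    norm_mode: str = "total_binomial",
) -> DivergenceReport:
    """End-to-end divergence statistics for a frequency panel."""
    norm = genotype_moments(structure, freqs, mode=norm_mode)
    summary = egrm_elements(structure, freqs, norm)
    spec = structural_spectrum(summary, structure)
    sigma_b2, sigma_w2 = variance_components(summary, structure)
    return DivergenceReport(
        sigma_b2=sigma_b2,
        sigma_w2=sigma_w2,
        f_pc=fpc(sigma_b2, sigma_w2),
        f_pc_star=fpc_star(sigma_b2, sigma_w2),
        d2=pop_distance_d2(spec.eigenvalues, summary, structure),
        k_pcs=structure.n_populations,
        n_samples=structure.n_samples,
        n_snps=freqs.n_snps,
        norm_mode=norm_mode,
    )
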