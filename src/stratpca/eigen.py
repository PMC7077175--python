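"""Eigen-analysis of relationship matrices.

Two complementary routes are provided.  :func:`full_spectrum` is the plain
numeric symmetric eigendecomposition used for PCA of an observed GRM.  For
a theoretical EGRM the spectrum has exact structure: each population
contributes N_k - 1 "intra" eigenvalues equal to z^k - z^kk, and the
remaining K "structural" eigenvalues - the ones carrying all
inter-population variance - are the eigenvalues of the K x K reduced
matrix

    B_kk = (z^k - z^kk) + N_k z^kk,     B_kl = sqrt(N_k N_l) z^kl  (k != l),

whose eigenvectors map back to block-constant length-N eigenvectors with
value u_k / sqrt(N_k) inside block k.  :func:`structural_spectrum` computes
this exact decomposition; it separates structural from intra eigenvalues
even when they are numerically degenerate, which magnitude-sorting of the
full spectrum cannot do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .egrm import EMPIRICAL_GRM, THEORETICAL_EGRM, BlockSummary, RelationshipMatrix
from .model import PopulationStructure, StructureError

__all__ = [
    "EigenResult",
    "StructuralSpectrum",
    "full_spectrum",
    "structural_spectrum",
    "two_pop_eigenvalues",
    "variance_explained_topk",
    "representative_points",
    "approximate_representative_points",
]


def _fix_signs(vectors: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Deterministic sign convention: largest-magnitude entry positive,
    ties broken by lowest index."""
    v = vectors.copy()
    for j in range(v.shape[1]):
        col = v[:, j]
        amax = np.abs(col).max()
        idx = int(np.flatnonzero(np.abs(col) >= amax - tol)[0])
        if col[idx] < 0:
            v[:, j] = -col
    return v


@dataclass
class EigenResult:
    """Full spectrum of a relationship matrix, sorted descending."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns paired to eigenvalues
    variance_explained: np.ndarray
    kind: str
    structural_indices: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.eigenvalues.size


@dataclass
class StructuralSpectrum:
    """Exact eigenstructure of an EGRM split into structural and intra parts.

    ``eigenvalues``/``eigenvectors`` are the K structural eigenpairs
    (block-constant, descending); ``block_values[j, k]`` is the constant
    eigenvector entry of population k in structural dimension j.  The
    remaining N - K eigenvalues are ``intra_values[k]`` = z^k - z^kk, each
    with multiplicity N_k - 1.
    """

    eigenvalues: np.ndarray  # (K,)
    eigenvectors: np.ndarray  # (N, K)
    block_values: np.ndarray  # (K_dims, K_pops)
    intra_values: np.ndarray  # (K,)
    intra_multiplicities: np.ndarray  # (K,), N_k - 1

    @property
    def n_structural(self) -> int:
        return self.eigenvalues.size

    def all_eigenvalues(self) -> np.ndarray:
        """Complete length-N spectrum (structural + analytic intra), descending."""
        full = np.concatenate(
            [self.eigenvalues, np.repeat(self.intra_values, self.intra_multiplicities)]
        )
        return np.sort(full)[::-1]


def full_spectrum(
    matrix: RelationshipMatrix,
    summary: BlockSummary | None = None,
    structure: PopulationStructure | None = None,
    *,
    sym_tol: float = 1e-8,
) -> EigenResult:
    """Complete numeric eigendecomposition, eigenvalues descending.

    If ``summary`` and ``structure`` are given for a theoretical EGRM, the
    indices of the K structural eigenvalues within the full spectrum are
    identified by matching against the reduced-matrix eigenvalues.
    """
    z = matrix.values
    if not np.allclose(z, z.T, atol=sym_tol):
        raise StructureError("matrix is not symmetric within tolerance")
    w, v = np.linalg.eigh((z + z.T) / 2.0)
    order = np.argsort(w)[::-1]
    w = w[order]
    v = _fix_signs(v[:, order])
    total = w.sum()
    ve = w / total if total != 0 else np.full_like(w, np.nan)

    structural_indices = None
    if summary is not None and structure is not None:
        if matrix.kind != THEORETICAL_EGRM:
            raise StructureError(
                "structural indices are defined for theoretical EGRMs only"
            )
        spec = structural_spectrum(summary, structure)
        structural_indices = _match_indices(w, spec.eigenvalues)
    return EigenResult(
        eigenvalues=w,
        eigenvectors=v,
        variance_explained=ve,
        kind=matrix.kind,
        structural_indices=structural_indices,
    )


def _match_indices(full: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Greedy nearest-value matching of target eigenvalues to spectrum indices."""
    used = np.zeros(full.size, dtype=bool)
    out = np.empty(targets.size, dtype=np.int64)
    for i, t in enumerate(targets):
        dist = np.abs(full - t)
        dist[used] = np.inf
        j = int(np.argmin(dist))
        used[j] = True
        out[i] = j
    return out


def structural_spectrum(
    summary: BlockSummary, structure: PopulationStructure
) -> StructuralSpectrum:
    """Exact structural + intra eigenstructure from the K x K reduced matrix."""
    k = structure.n_populations
    if summary.n_populations != k:
        raise StructureError("summary and structure population counts differ")
    if np.any(~np.isfinite(summary.zkk)):
        raise StructureError(
            "block summary has missing within-population covariances"
        )
    sizes = structure.sizes.astype(float)
    intra = summary.zk - summary.zkk
    b = np.sqrt(np.outer(sizes, sizes)) * summary.zkl
    np.fill_diagonal(b, intra + sizes * summary.zkk)
    w, u = np.linalg.eigh(b)
    order = np.argsort(w)[::-1]
    w = w[order]
    u = u[:, order]
    # map K-vectors back to block-constant length-N eigenvectors
    block_values = (u / np.sqrt(sizes)[:, None]).T  # (K_dims, K_pops)
    block_values = _fix_signs(block_values.T).T
    vectors = block_values[:, structure.membership].T  # (N, K)
    return StructuralSpectrum(
        eigenvalues=w,
        eigenvectors=vectors,
        block_values=block_values,
        intra_values=intra,
        intra_multiplicities=structure.sizes - 1,
    )


def two_pop_eigenvalues(
    summary: BlockSummary, structure: PopulationStructure
) -> tuple[float, float]:
    """Closed-form structural eigenvalues for exactly two populations.

    lambda_{1,2} = [N1 z11 + N2 z22 + (z1 - z11) + (z2 - z22) +- sqrt(a)] / 2
    with a = [(z1 - z11) - (z2 - z22) + N1 z11 - N2 z22]^2 + 4 N1 N2 (z12)^2.
    """
    if structure.n_populations != 2 or summary.n_populations != 2:
        raise StructureError("closed form requires exactly two populations")
    n1, n2 = structure.sizes.astype(float)
    z1, z2 = summary.zk
    z11, z22 = summary.zkk
    z12 = summary.zkl[0, 1]
    i1 = z1 - z11
    i2 = z2 - z22
    a = (i1 - i2 + n1 * z11 - n2 * z22) ** 2 + 4.0 * n1 * n2 * z12**2
    half = (n1 * z11 + n2 * z22 + i1 + i2) / 2.0
    root = np.sqrt(a) / 2.0
    return float(half + root), float(half - root)


def variance_explained_topk(result: EigenResult, k: int) -> float:
    """Fraction of total variance (trace) carried by the largest k eigenvalues."""
    if not 1 <= k <= result.n:
        raise ValueError(f"k must be in [1, {result.n}], got {k}")
    return float(result.eigenvalues[:k].sum() / result.eigenvalues.sum())


def representative_points(
    spectrum: StructuralSpectrum, structure: PopulationStructure
) -> tuple[np.ndarray, np.ndarray]:
    """Population centers and the grand center in sqrt(lambda)-scaled
    structural coordinates.

    Returns ``(centers, grand)`` where ``centers[k, j]`` is the coordinate
    of population k in structural dimension j (all members of a population
    share it exactly) and ``grand[j]`` is the total-population center.

    Exact centers exist only for a theoretical EGRM; for an observed GRM
    pass its :class:`EigenResult` to
    :func:`approximate_representative_points` instead.
    """
    if isinstance(spectrum, EigenResult):
        if spectrum.kind == EMPIRICAL_GRM:
            raise StructureError(
                "empirical GRM eigenvectors are not block-constant; use "
                "approximate_representative_points"
            )
        raise StructureError(
            "exact representative points require the structural spectrum "
            "(use structural_spectrum); numeric eigenvectors mix structural "
            "and intra directions in degenerate eigenspaces"
        )
    lam = np.clip(spectrum.eigenvalues, 0.0, None)
    scale = np.sqrt(lam)  # (K_dims,)
    centers = (scale[:, None] * spectrum.block_values).T  # (K_pops, K_dims)
    weights = structure.sizes / structure.n_samples
    grand = weights @ centers
    return centers, grand


def approximate_representative_points(
    result: EigenResult, structure: PopulationStructure, n_dims: int
) -> tuple[np.ndarray, np.ndarray]:
    """Within-population means of sqrt(lambda)-scaled sample coordinates.

    Approximate analogue of :func:`representative_points` for an observed
    GRM, whose eigenvectors are only approximately block-constant.
    """
    if result.n != structure.n_samples:
        raise StructureError("eigen result does not match structure")
    if not 1 <= n_dims <= result.n:
        raise ValueError("n_dims out of range")
    lam = np.clip(result.eigenvalues[:n_dims], 0.0, None)
    coords = result.eigenvectors[:, :n_dims] * np.sqrt(lam)  # (N, n_dims)
    centers = np.stack(
        [coords[s].mean(axis=0) for s in structure.block_slices()]
    )
    grand = coords.mean(axis=0)
    return centers, grand
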