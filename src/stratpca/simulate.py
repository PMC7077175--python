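"""Synthetic multi-population genotype and frequency-panel generation.

Genotypes are independent two-trial binomial draws at each individual's
population allele frequency (Hardy-Weinberg equilibrium within population,
no linkage disequilibrium) - exactly the data-generating model the EGRM
theory describes.  Frequency panels are drawn with a Balding-Nichols
perturbation: the per-population frequency of a SNP with pooled frequency
f is Beta-distributed with mean f and variance F f (1 - f), where the
``divergence`` parameter F plays the role of a target F_ST.  F = 0.1 is a
continental-human-scale default; F = 0 makes all populations identical.

Randomness uses a single integer master seed; replicate substreams are
spawned from it with ``numpy.random.SeedSequence`` so experiments are
reproducible and order-independent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .egrm import egrm_elements
from .grm import block_summaries, compute_grm, estimate_norm_params, normalize_genotypes
from .model import (
    AlleleFrequencyTable,
    GenotypeMatrix,
    PopulationStructure,
    genotype_moments,
    maf_bin_range,
)

__all__ = ["simulate_genotypes", "draw_frequency_panel", "convergence_experiment"]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_genotypes(
    structure: PopulationStructure,
    freqs: AlleleFrequencyTable,
    seed: int | np.random.Generator = 0,
) -> GenotypeMatrix:
    """Draw an N x M genotype matrix: X(n, m) ~ Binomial(2, f_km)."""
    if structure.n_populations != freqs.n_populations:
        raise ValueError("structure and frequency table population counts differ")
    rng = _as_rng(seed)
    probs = freqs.freqs[structure.membership]  # (N, M)
    x = rng.binomial(2, probs).astype(np.int8)
    return GenotypeMatrix(
        values=x,
        sample_ids=structure.default_sample_ids(),
        snp_ids=list(freqs.snp_ids),
    )


def draw_frequency_panel(
    structure: PopulationStructure,
    n_snps: int,
    maf_bin: int | None = None,
    maf_range: tuple[float, float] | None = None,
    divergence: float = 0.1,
    seed: int | np.random.Generator = 0,
    max_tries: int = 1000,
) -> AlleleFrequencyTable:
    """Random frequency panel whose pooled MAF lies in a bin or (lo, hi] range.

    For each SNP a pooled target frequency is drawn uniformly in the MAF
    interval (the coded allele is the minor one), per-population
    frequencies are drawn Balding-Nichols around it, and the draw is
    accepted once the realized size-weighted pooled MAF falls in the
    interval and the SNP is polymorphic in the pooled sample.  Individual
    populations may be monomorphic, as real rare variants are.
    """
    if (maf_bin is None) == (maf_range is None):
        raise ValueError("specify exactly one of maf_bin or maf_range")
    lo, hi = maf_bin_range(maf_bin) if maf_bin is not None else maf_range
    if not (0 <= lo < hi <= 0.5):
        raise ValueError(f"infeasible MAF interval ({lo}, {hi}]")
    if divergence < 0 or divergence >= 1:
        raise ValueError("divergence must lie in [0, 1)")
    rng = _as_rng(seed)
    k = structure.n_populations
    w = structure.weights
    out = np.empty((k, n_snps))
    for m in range(n_snps):
        for _ in range(max_tries):
            f = rng.uniform(lo, hi)
            if divergence == 0.0:
                fk = np.full(k, f)
            else:
                a = f * (1.0 - divergence) / divergence
                b = (1.0 - f) * (1.0 - divergence) / divergence
                fk = rng.beta(a, b, size=k)
            total = float(w @ fk)
            maf = min(total, 1.0 - total)
            if 0.0 < total < 1.0 and lo < maf <= hi:
                out[:, m] = fk
                break
        else:
            raise RuntimeError(
                f"could not draw a SNP in MAF interval ({lo}, {hi}] "
                f"with divergence {divergence} after {max_tries} tries"
            )
    snp_ids = [f"snp{m + 1}" for m in range(n_snps)]
    return AlleleFrequencyTable(snp_ids=snp_ids, freqs=out)


def convergence_experiment(
    structure: PopulationStructure,
    freqs: AlleleFrequencyTable,
    reps: int,
    mode: str = "known",
    seed: int = 0,
    norm_mode: str = "total_binomial",
) -> pd.DataFrame:
    """Replicate comparison of theoretical vs empirical z^k, z^kk.

    For each replicate, genotypes are simulated, the GRM computed with
    either known moments (``mode='known'``: ``norm_mode`` moments at the
    true frequencies) or per-replicate estimated moments
    (``mode='estimated'``: the GCTA-style 2 f_hat (1 - f_hat) convention at
    sample frequencies), and block-averaged.  SNPs monomorphic in a
    replicate are dropped for that replicate in estimated mode.

    Returns a table with one row per population: theoretical values,
    replicate means, Monte-Carlo standard errors and the mean number of
    dropped SNPs per replicate.
    """
    if reps < 2:
        raise ValueError("need at least 2 replicates")
    if mode not in ("known", "estimated"):
        raise ValueError("mode must be 'known' or 'estimated'")

    norm_known = genotype_moments(structure, freqs, mode=norm_mode)
    theory = egrm_elements(structure, freqs, norm_known)

    k = structure.n_populations
    zk_reps = np.full((reps, k), np.nan)
    zkk_reps = np.full((reps, k), np.nan)
    dropped = np.zeros(reps, dtype=int)

    streams = np.random.SeedSequence(seed).spawn(reps)
    for r in range(reps):
        rng = np.random.default_rng(streams[r])
        geno = simulate_genotypes(structure, freqs, rng)
        if mode == "known":
            y = normalize_genotypes(geno, norm_known, strict=True)
        else:
            norm_hat = estimate_norm_params(geno, mode="gcta", strict=False)
            n_bad = int((norm_hat.sigma <= 0).sum())
            dropped[r] = n_bad
            if n_bad == geno.n_snps:
                continue  # all SNPs monomorphic in this replicate
            y = normalize_genotypes(geno, norm_hat, strict=False)
        summary = block_summaries(compute_grm(y, structure=structure), structure)
        zk_reps[r] = summary.zk
        zkk_reps[r] = summary.zkk

    def _mean_se(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n_ok = np.sum(~np.isnan(a), axis=0)
        mean = np.nanmean(a, axis=0)
        se = np.nanstd(a, axis=0, ddof=1) / np.sqrt(np.maximum(n_ok, 1))
        return mean, se

    zk_mean, zk_se = _mean_se(zk_reps)
    zkk_mean, zkk_se = _mean_se(zkk_reps)
    table = pd.DataFrame(
        {
            "population": structure.labels,
            "n": structure.sizes,
            "z_k_theory": theory.zk,
            "z_k_mean": zk_mean,
            "z_k_se": zk_se,
            "z_kk_theory": theory.zkk,
            "z_kk_mean": zkk_mean,
            "z_kk_se": zkk_se,
            "snps_dropped_mean": np.full(k, dropped.mean()),
        }
    )
    table.attrs.update(
        {"mode": mode, "reps": reps, "seed": seed, "norm_mode": norm_mode}
    )
    return table
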