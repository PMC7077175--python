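"""Plain-text readers and writers for the shared formats.

Formats (all tab-separated):

* frequency table - ``#size<TAB>pop<TAB>N_k`` header lines (or a sidecar
  sizes file of ``pop<TAB>N_k`` rows), then a ``snp_id<TAB>pop1<TAB>...``
  header and one row per SNP with frequencies in [0, 1];
* labels - ``sample_id<TAB>population`` rows, block-contiguous by population;
* genotypes - ``tsv`` dialect: samples x SNPs with row/column headers;
  ``traw`` dialect: PLINK transposed raw text (SNP rows, leading columns
  CHR SNP (C)M POS COUNTED ALT, then per-sample counts of the COUNTED
  allele).  Missing values are rejected;
* square relationship matrix with a header row of sample ids (GCTA-like
  plain-text convention);
* eigenvalues (one per line) and eigenvectors
  (``sample_id population PC1 PC2 ...``);
* divergence report as flat key-value rows.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .egrm import RelationshipMatrix
from .model import (
    AlleleFrequencyTable,
    GenotypeMatrix,
    PopulationStructure,
    StructureError,
)

__all__ = [
    "ParseError",
    "read_frequency_table",
    "write_frequency_table",
    "read_labels",
    "write_labels",
    "read_genotypes",
    "write_genotypes_tsv",
    "reorder_samples",
    "read_matrix",
    "write_matrix",
    "write_eigenval",
    "write_eigenvec",
    "write_report",
]

DEFAULT_PRECISION = 6


class ParseError(ValueError):
    """Malformed input file; message carries the file and line number."""


def _fmt(x: float, precision: int) -> str:
    return f"{x:.{precision}g}"


# ---------------------------------------------------------------- frequencies


def write_frequency_table(
    path,
    structure: PopulationStructure,
    freqs: AlleleFrequencyTable,
    precision: int = DEFAULT_PRECISION,
) -> None:
    if structure.n_populations != freqs.n_populations:
        raise StructureError("structure and frequency table population counts differ")
    lines = [
        f"#size\t{lab}\t{int(n)}" for lab, n in zip(structure.labels, structure.sizes)
    ]
    lines.append("snp_id\t" + "\t".join(structure.labels))
    for m, snp in enumerate(freqs.snp_ids):
        row = "\t".join(_fmt(v, precision) for v in freqs.freqs[:, m])
        lines.append(f"{snp}\t{row}")
    Path(path).write_text("\n".join(lines) + "\n")


def _read_sizes_sidecar(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}:{i}: expected 'population<TAB>size'")
        try:
            sizes[parts[0]] = int(parts[1])
        except ValueError:
            raise ParseError(f"{path}:{i}: size {parts[1]!r} is not an integer") from None
    return sizes


def read_frequency_table(
    path, sizes_path=None
) -> tuple[AlleleFrequencyTable, PopulationStructure]:
    """Read a frequency table plus its population sizes.

    Sizes come from ``#size`` header lines in the file itself or, if absent,
    from a sidecar file of ``population<TAB>size`` rows.
    """
    sizes: dict[str, int] = {}
    header: list[str] | None = None
    snp_ids: list[str] = []
    rows: list[list[float]] = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("#size"):
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(f"{path}:{i}: expected '#size<TAB>pop<TAB>N'")
            try:
                sizes[parts[1]] = int(parts[2])
            except ValueError:
                raise ParseError(f"{path}:{i}: size {parts[2]!r} is not an integer") from None
            continue
        if line.startswith("#"):
            continue
        parts = line.split("\t")
        if header is None:
            if parts[0] != "snp_id" or len(parts) < 2:
                raise ParseError(f"{path}:{i}: expected header 'snp_id<TAB>pop1<TAB>...'")
            header = parts[1:]
            continue
        if len(parts) != len(header) + 1:
            raise ParseError(
                f"{path}:{i}: expected {len(header) + 1} fields, got {len(parts)}"
            )
        if parts[0] in snp_ids:
            raise ParseError(f"{path}:{i}: duplicate SNP id {parts[0]!r}")
        try:
            vals = [float(v) for v in parts[1:]]
        except ValueError:
            raise ParseError(f"{path}:{i}: non-numeric frequency") from None
        for v in vals:
            if not 0.0 <= v <= 1.0:
                raise ParseError(f"{path}:{i}: frequency {v} outside [0, 1]")
        snp_ids.append(parts[0])
        rows.append(vals)
    if header is None or not rows:
        raise ParseError(f"{path}: no frequency rows found")
    if not sizes:
        if sizes_path is None:
            raise ParseError(
                f"{path}: population sizes missing (no #size lines and no sizes file)"
            )
        sizes = _read_sizes_sidecar(sizes_path)
    missing = [p for p in header if p not in sizes]
    if missing:
        raise ParseError(f"{path}: no size given for population(s) {missing}")
    structure = PopulationStructure(
        labels=header, sizes=np.array([sizes[p] for p in header])
    )
    table = AlleleFrequencyTable(snp_ids=snp_ids, freqs=np.array(rows).T)
    return table, structure


# --------------------------------------------------------------------- labels


def write_labels(path, structure: PopulationStructure, sample_ids=None) -> None:
    ids = sample_ids if sample_ids is not None else structure.default_sample_ids()
    mem = structure.membership
    lines = [f"{sid}\t{structure.labels[p]}" for sid, p in zip(ids, mem)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_labels(path) -> tuple[list[str], PopulationStructure]:
    """Read sample labels; populations must occupy contiguous blocks."""
    sample_ids: list[str] = []
    pops: list[str] = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}:{i}: expected 'sample_id<TAB>population'")
        sample_ids.append(parts[0])
        pops.append(parts[1])
    if not sample_ids:
        raise ParseError(f"{path}: empty labels file")
    labels: list[str] = []
    sizes: list[int] = []
    for p in pops:
        if labels and p == labels[-1]:
            sizes[-1] += 1
        elif p in labels:
            raise ParseError(
                f"{path}: population {p!r} is not block-contiguous; "
                "sort samples by population first"
            )
        else:
            labels.append(p)
            sizes.append(1)
    return sample_ids, PopulationStructure(labels=labels, sizes=np.array(sizes))


# ------------------------------------------------------------------ genotypes

_TRAW_META = ["CHR", "SNP", "(C)M", "POS", "COUNTED", "ALT"]


def read_genotypes(path, dialect: str = "tsv") -> GenotypeMatrix:
    """Read genotypes; ``tsv`` is samples x SNPs, ``traw`` is PLINK
    transposed raw (SNPs x samples).  Missing values are rejected."""
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.isna().any().any():
            raise ParseError(f"{path}: missing genotype values are not supported")
        return GenotypeMatrix(
            values=df.to_numpy(),
            sample_ids=[str(s) for s in df.index],
            snp_ids=[str(s) for s in df.columns],
        )
    if dialect == "traw":
        df = pd.read_csv(path, sep="\t")
        meta = [c for c in _TRAW_META if c in df.columns]
        if "SNP" not in meta or "COUNTED" not in meta:
            raise ParseError(f"{path}: not a traw file (missing SNP/COUNTED columns)")
        samples = [c for c in df.columns if c not in _TRAW_META]
        if not samples:
            raise ParseError(f"{path}: traw file has no sample columns")
        counts = df[samples]
        if counts.isna().any().any():
            raise ParseError(f"{path}: missing genotype values (NA) are not supported")
        return GenotypeMatrix(
            values=counts.to_numpy().T,
            sample_ids=[str(s) for s in samples],
            snp_ids=[str(s) for s in df["SNP"]],
        )
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def write_genotypes_tsv(path, genotypes: GenotypeMatrix) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(genotypes.snp_ids) + "\n")
        for sid, row in zip(genotypes.sample_ids, genotypes.values):
            fh.write(sid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def reorder_samples(genotypes: GenotypeMatrix, sample_ids: list[str]) -> GenotypeMatrix:
    """Reorder genotype rows to a given sample order (e.g. a labels file)."""
    index = {s: i for i, s in enumerate(genotypes.sample_ids)}
    missing = [s for s in sample_ids if s not in index]
    if missing or len(sample_ids) != genotypes.n_samples:
        raise StructureError(
            f"label/genotype sample mismatch (missing: {missing[:5]})"
        )
    order = [index[s] for s in sample_ids]
    return GenotypeMatrix(
        values=genotypes.values[order],
        sample_ids=list(sample_ids),
        snp_ids=list(genotypes.snp_ids),
    )


# ------------------------------------------------------------------- matrices


def write_matrix(
    path, matrix: RelationshipMatrix, precision: int = DEFAULT_PRECISION
) -> None:
    ids = matrix.sample_ids or [f"s{i + 1}" for i in range(matrix.n_samples)]
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(ids) + "\n")
        for sid, row in zip(ids, matrix.values):
            fh.write(sid + "\t" + "\t".join(_fmt(v, precision) for v in row) + "\n")


def read_matrix(path, kind: str = "empirical-GRM") -> RelationshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ParseError(f"{path}: matrix is not square ({df.shape})")
    values = df.to_numpy(dtype=float)
    values = (values + values.T) / 2.0  # symmetrize text round-off
    return RelationshipMatrix(
        values=values, kind=kind, sample_ids=[str(s) for s in df.index]
    )


# ---------------------------------------------------------------- eigen files


def write_eigenval(path, eigenvalues, precision: int = DEFAULT_PRECISION) -> None:
    Path(path).write_text(
        "\n".join(_fmt(v, precision) for v in np.asarray(eigenvalues)) + "\n"
    )


def write_eigenvec(
    path,
    sample_ids,
    populations,
    coords: np.ndarray,
    precision: int = DEFAULT_PRECISION,
) -> None:
    """Per-sample rows of ``sample_id population PC1 PC2 ...``."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    header = "sample_id\tpopulation\t" + "\t".join(
        f"PC{j + 1}" for j in range(coords.shape[1])
    )
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for sid, pop, row in zip(sample_ids, populations, coords):
            fh.write(
                f"{sid}\t{pop}\t" + "\t".join(_fmt(v, precision) for v in row) + "\n"
            )


# -------------------------------------------------------------------- reports


def write_report(path, values: dict, precision: int = DEFAULT_PRECISION) -> None:
    """Flat key-value TSV."""
    with open(path, "w") as fh:
        for key, val in values.items():
            out = _fmt(val, precision) if isinstance(val, float) else str(val)
            fh.write(f"{key}\t{out}\n")
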