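"""File formats: genotype tables, VCF, kinship matrices, result tables.

The canonical genotype format is a whitespace-delimited table — one row
per individual, columns ``id ploidy locus1 locus2 ...`` with each locus
cell a comma-separated allele list ("." for a missing copy or a fully
missing genotype).  Allele labels are arbitrary strings, so microsatellite
repeat numbers and SNP bases both work.  VCF is supported as a convenience
reader for SNP data (via cyvcf2); per-genotype ploidy is inferred from the
GT field (haploid "0", diploid "0/1", ...).

Kinship matrices travel as labeled square TSV: first row and first column
are sample ids, the body is the symmetric matrix at full float precision.
"""

from __future__ import annotations

import sys
from typing import Optional, Sequence, TextIO

import numpy as np
import pandas as pd

from . import __version__
from .errors import BesthetError, GenotypeError
from .frequency import GenotypeSample
from .pedigree import KinshipSpec

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_kinship",
    "write_kinship",
    "write_results",
]


def _parse_cell(cell: str, ploidy: int, ind: str, locus: str) -> tuple:
    cell = cell.strip()
    if cell == "." or cell == "":
        return tuple([None] * ploidy)
    parts = [p.strip() for p in cell.split(",")]
    if len(parts) != ploidy:
        raise GenotypeError(
            f"individual {ind!r}, locus {locus!r}: {len(parts)} alleles "
            f"but ploidy {ploidy}"
        )
    return tuple(None if p == "." else p for p in parts)


def _read_table(path) -> dict[str, GenotypeSample]:
    header: Optional[list[str]] = None
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if header is None:
                    header = line.lstrip("#").split()
                continue
            rows.append(line.split())
    if not rows:
        raise GenotypeError(f"no genotype rows in {path}")
    n_loci = len(rows[0]) - 2
    if n_loci < 1:
        raise GenotypeError("genotype table needs id, ploidy and >= 1 locus column")
    if header is not None and len(header) >= 2 + n_loci:
        loci = header[2 : 2 + n_loci]
    else:
        loci = [f"locus{i + 1}" for i in range(n_loci)]

    ids, ploidies, cells = [], [], []
    for row in rows:
        if len(row) != 2 + n_loci:
            raise GenotypeError(f"ragged genotype row: {' '.join(row)!r}")
        ids.append(row[0])
        try:
            ploidies.append(int(row[1]))
        except ValueError:
            raise GenotypeError(f"bad ploidy {row[1]!r} for {row[0]!r}") from None
        cells.append(row[2:])

    out: dict[str, GenotypeSample] = {}
    for j, locus in enumerate(loci):
        alleles = [
            _parse_cell(cells[k][j], ploidies[k], ids[k], locus)
            for k in range(len(ids))
        ]
        out[locus] = GenotypeSample(list(ids), np.array(ploidies), alleles, locus=locus)
    return out


def _read_vcf(path) -> dict[str, GenotypeSample]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    out: dict[str, GenotypeSample] = {}
    for var in vcf:
        labels = [var.REF] + list(var.ALT)
        locus = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        ploidies, alleles = [], []
        for g in var.genotypes:
            calls = g[:-1]  # last entry is phase flag
            ploidies.append(len(calls))
            alleles.append(
                tuple(None if a < 0 else labels[a] for a in calls)
            )
        out[locus] = GenotypeSample(
            list(ids), np.array(ploidies), alleles, locus=locus,
            declared_alleles=labels,
        )
    return out


def read_genotypes(path, format: str = "table") -> dict[str, GenotypeSample]:
    """Read per-locus genotype samples from a table or a VCF.

    Returns a dict mapping locus id to :class:`GenotypeSample`.
    """
    if format == "table":
        return _read_table(path)
    if format == "vcf":
        return _read_vcf(path)
    raise BesthetError(f"unknown genotype format {format!r} (use 'table' or 'vcf')")


def write_genotypes(samples: Sequence[GenotypeSample], path) -> None:
    """Write one or more loci (same individuals) as a genotype table."""
    samples = list(samples)
    ids = samples[0].ids
    ploidies = samples[0].ploidies
    for s in samples[1:]:
        if s.ids != ids or not np.array_equal(s.ploidies, ploidies):
            raise BesthetError("all loci must share the same individuals")

    def _emit(fh: TextIO) -> None:
        fh.write("#id ploidy " + " ".join(s.locus for s in samples) + "\n")
        for k, ind in enumerate(ids):
            cells = []
            for s in samples:
                g = s.alleles[k]
                cells.append(",".join("." if a is None else str(a) for a in g))
            fh.write(f"{ind} {ploidies[k]} " + " ".join(cells) + "\n")

    if hasattr(path, "write"):
        _emit(path)
    else:
        with open(path, "w") as fh:
            _emit(fh)


def read_kinship(path) -> KinshipSpec:
    """Read a labeled square kinship TSV (symmetrized within 1e-9)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise BesthetError(f"kinship matrix must be square, got {df.shape}")
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if row_ids != col_ids:
        raise BesthetError("kinship row and column labels differ")
    M = df.to_numpy(dtype=float)
    if not np.allclose(M, M.T, atol=1e-9):
        raise BesthetError("kinship matrix asymmetric beyond 1e-9 tolerance")
    return KinshipSpec(row_ids, 0.5 * (M + M.T))


def write_kinship(K: KinshipSpec, path) -> None:
    """Write a kinship matrix as labeled TSV at full float precision."""
    df = pd.DataFrame(K.matrix, index=K.sample_ids, columns=K.sample_ids)
    df.to_csv(path, sep="\t", float_format="%.17g")


def write_results(
    rows: Sequence[dict],
    out: Optional[TextIO | str] = None,
    metadata: Optional[dict] = None,
) -> None:
    """Write a result table as TSV with a commented ``# key=value`` header."""
    meta = {"software": f"besthet {__version__}"}
    meta.update(metadata or {})

    def _emit(fh: TextIO) -> None:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        if rows:
            cols = list(rows[0])
            fh.write("\t".join(cols) + "\n")
            for r in rows:
                fh.write("\t".join(str(r[c]) for c in cols) + "\n")

    if out is None:
        _emit(sys.stdout)
    elif isinstance(out, (str, bytes)) or hasattr(out, "__fspath__"):
        with open(out, "w") as fh:
            _emit(fh)
    else:
        _emit(out)
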