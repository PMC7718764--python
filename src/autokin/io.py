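"""Plain-text file formats.

Everything is CSV/TSV with documented headers; the missing-value token is
``NA``.  All readers and writers round-trip losslessly and preserve
individual and locus order.

* dosage CSV — first column ``id``, one column per locus, integer dosages
  0..2v or ``NA``.
* multiallelic TSV — first column ``id``, one column per locus, the 2v
  allele codes joined by ``/`` (e.g. ``3/3/7/12`` for a tetraploid);
  ``NA`` for a missing call.
* relationship matrix CSV — square, id header row and column; also a long
  form ``id1,id2,r``.
* genetic map TSV — ``marker, chromosome, position_cM``.
* inbreeding CSV — ``id, F``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import (
    MISSING_ALLELE,
    DosageMatrix,
    InbreedingVector,
    MultiallelicGenotypes,
    RelationshipMatrix,
)
from .genome import GenomeMap

__all__ = [
    "read_dosage",
    "write_dosage",
    "read_multiallelic",
    "write_multiallelic",
    "read_matrix",
    "write_matrix",
    "write_matrix_long",
    "read_map",
    "write_map",
    "write_inbreeding",
]

NA = "NA"


def write_dosage(d: DosageMatrix, path) -> None:
    df = pd.DataFrame(d.values, index=d.ids, columns=d.loci)
    df.index.name = "id"
    out = df.map(lambda x: NA if not np.isfinite(x) else str(int(x)))
    out.to_csv(path)


def read_dosage(path, ploidy: int) -> DosageMatrix:
    """Read a dosage CSV; every value must lie in 0..2v or be ``NA``."""
    df = pd.read_csv(path, index_col=0, dtype=str)
    vals = np.empty(df.shape, dtype=float)
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = str(df.iat[i, j]).strip()
            if cell.upper() in (NA, "NAN", ""):
                vals[i, j] = np.nan
                continue
            try:
                x = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric dosage {cell!r} at "
                    f"({df.index[i]}, {df.columns[j]})"
                ) from None
            if not 0 <= x <= ploidy or x != int(x):
                raise ValueError(
                    f"dosage {cell} out of 0..{ploidy} at "
                    f"({df.index[i]}, {df.columns[j]})"
                )
            vals[i, j] = x
    return DosageMatrix(
        ids=[str(i) for i in df.index],
        loci=[str(c) for c in df.columns],
        ploidy=ploidy,
        values=vals,
    )


def write_multiallelic(g: MultiallelicGenotypes, path) -> None:
    cells = []
    for i in range(g.n):
        row = []
        for l in range(g.n_loci):
            a = g.alleles[i, :, l]
            row.append(
                NA if (a == MISSING_ALLELE).any()
                else "/".join(str(int(x)) for x in a)
            )
        cells.append(row)
    df = pd.DataFrame(cells, index=g.ids, columns=g.loci)
    df.index.name = "id"
    df.to_csv(path, sep="\t")


def read_multiallelic(path, ploidy: int) -> MultiallelicGenotypes:
    """Read a multiallelic TSV; each cell must have exactly 2v ``/``-joined
    positive integer allele codes, or be ``NA``."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    n, L = df.shape
    alleles = np.full((n, ploidy, L), MISSING_ALLELE, dtype=np.int64)
    for i in range(n):
        for l in range(L):
            cell = str(df.iat[i, l]).strip()
            if cell.upper() in (NA, "NAN", ""):
                continue
            parts = cell.split("/")
            if len(parts) != ploidy:
                raise ValueError(
                    f"genotype {cell!r} at ({df.index[i]}, {df.columns[l]}) "
                    f"has {len(parts)} alleles, expected {ploidy}"
                )
            codes = [int(p) for p in parts]
            if any(c <= 0 for c in codes):
                raise ValueError(
                    f"allele codes must be positive integers, got {cell!r}"
                )
            alleles[i, :, l] = codes
    return MultiallelicGenotypes(
        ids=[str(i) for i in df.index],
        loci=[str(c) for c in df.columns],
        ploidy=ploidy,
        alleles=alleles,
    )


def write_matrix(rm: RelationshipMatrix, path) -> None:
    df = pd.DataFrame(rm.values, index=rm.ids, columns=rm.ids)
    df.index.name = "id"
    df.to_csv(path, na_rep=NA)


def read_matrix(path, atol: float = 1e-9) -> RelationshipMatrix:
    """Read a square relationship CSV; asymmetries beyond ``atol`` are
    rejected."""
    df = pd.read_csv(path, index_col=0)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError("matrix row and column ids differ")
    vals = df.to_numpy(dtype=float)
    finite = np.isfinite(vals)
    sym = finite & finite.T
    if not np.allclose(vals[sym], vals.T[sym], atol=atol):
        raise ValueError(f"matrix asymmetric beyond tolerance {atol}")
    return RelationshipMatrix(
        ids=[str(i) for i in df.index], values=vals
    )


def write_matrix_long(rm: RelationshipMatrix, path) -> None:
    rm.to_long().to_csv(path, index=False, na_rep=NA)


def write_map(gm: GenomeMap, path) -> None:
    gm.to_frame().to_csv(path, sep="\t", index=False)


def read_map(path) -> GenomeMap:
    df = pd.read_csv(path, sep="\t")
    need = {"marker", "chromosome", "position_cM"}
    if not need.issubset(df.columns):
        raise ValueError(f"map file must have columns {sorted(need)}")
    names, lengths, positions = [], [], []
    for chrom, sub in df.groupby("chromosome", sort=False):
        pos = sub["position_cM"].to_numpy(dtype=float)
        names.append(str(chrom))
        lengths.append(float(pos[-1]))
        positions.append(pos)
    return GenomeMap(
        names=tuple(names),
        lengths=tuple(lengths),
        positions=tuple(positions),
    )


def write_inbreeding(iv: InbreedingVector, path) -> None:
    pd.DataFrame({"id": iv.ids, "F": iv.F}).to_csv(path, index=False)
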