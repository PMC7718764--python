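"""Marker bookkeeping: allele frequencies, similarity coefficients, and
conversion between multiallelic genotypes and biallelic dosages."""

from __future__ import annotations

import numpy as np

from .containers import (
    MISSING_ALLELE,
    DosageMatrix,
    MultiallelicGenotypes,
)

__all__ = [
    "allele_frequencies",
    "locus_similarity",
    "dosage_from_genotypes",
    "population_to_genotypes",
]


def allele_frequencies(g) -> list[dict]:
    """Sample allele frequencies per locus.

    Frequencies are plain counts over all genotyped allele slots of the
    full sample, focal pairs included — ``p_i = count_i / (2v * n)`` — with
    no small-sample correction.

    Parameters
    ----------
    g
        :class:`MultiallelicGenotypes` or :class:`DosageMatrix` (the
        latter returns the reference/alternate frequencies per locus).

    Returns
    -------
    list of dict
        One entry per locus with keys ``codes`` (sorted allele codes),
        ``p`` (frequencies summing to 1) and ``monomorphic`` (bool).
    """
    if isinstance(g, DosageMatrix):
        out = []
        for l in range(g.n_loci):
            col = g.values[:, l]
            col = col[np.isfinite(col)]
            if col.size == 0:
                raise ValueError(f"locus {g.loci[l]!r} is entirely missing")
            p_ref = col.sum() / (g.ploidy * col.size)
            out.append(
                {
                    "codes": np.array([0, 1]),
                    "p": np.array([1.0 - p_ref, p_ref]),
                    "monomorphic": p_ref in (0.0, 1.0),
                }
            )
        return out
    if not isinstance(g, MultiallelicGenotypes):
        raise TypeError("expected MultiallelicGenotypes or DosageMatrix")
    out = []
    for l in range(g.n_loci):
        a = g.alleles[:, :, l]
        a = a[a != MISSING_ALLELE]
        if a.size == 0:
            raise ValueError(f"locus {g.loci[l]!r} is entirely missing")
        codes, counts = np.unique(a, return_counts=True)
        p = counts / a.size
        out.append(
            {"codes": codes, "p": p, "monomorphic": codes.size == 1}
        )
    return out


def locus_similarity(g: MultiallelicGenotypes, l: int):
    """Similarity coefficients at one locus.

    Returns ``(codes, S, p)`` where ``S[x, i]`` is the within-genotype
    frequency of allele ``codes[i]`` in individual ``x`` (rows sum to 1
    for non-missing calls) and ``p`` are the sample allele frequencies.
    """
    a = g.alleles[:, :, l]
    obs = a[a != MISSING_ALLELE]
    codes = np.unique(obs)
    counts = (a[:, :, None] == codes[None, None, :]).sum(axis=1)
    S = counts / g.ploidy
    if obs.size:
        p = (obs[:, None] == codes[None, :]).sum(axis=0) / obs.size
    else:
        p = np.zeros(codes.size)
    return codes, S, np.asarray(p, dtype=float)


def dosage_from_genotypes(
    g: MultiallelicGenotypes, reference: int | None = None
) -> DosageMatrix:
    """Collapse biallelic multiallelic genotypes to reference-allele dosages.

    Exactly two allele codes may be present across the data set; the
    reference defaults to the lowest code.  Swapping the reference maps
    dosage ``d`` to ``2v - d``.
    """
    obs = g.alleles[g.alleles != MISSING_ALLELE]
    codes = np.unique(obs)
    if codes.size > 2:
        raise ValueError(
            f"dosage recoding needs <= 2 allele codes, found {codes.size}"
        )
    if reference is None:
        reference = int(codes.min())
    elif reference not in codes:
        raise ValueError(f"reference allele {reference} not observed")
    dosage = (g.alleles == reference).sum(axis=1).astype(float)
    dosage[(g.alleles == MISSING_ALLELE).any(axis=1)] = np.nan
    return DosageMatrix(
        ids=list(g.ids),
        loci=list(g.loci),
        ploidy=g.ploidy,
        values=dosage,
    )


def population_to_genotypes(pop, loci=None) -> MultiallelicGenotypes:
    """View a tracked population as multiallelic genotypes whose allele
    codes are the founder-origin labels (shifted to positive integers)."""
    alleles = pop.alleles + 1  # labels start at 0; codes must be positive
    names = pop.genome.locus_names()
    if loci is not None:
        idx = np.asarray(list(loci), dtype=int)
        alleles = alleles[:, :, idx]
        names = [names[i] for i in idx]
    return MultiallelicGenotypes(
        ids=list(pop.ids),
        loci=names,
        ploidy=pop.ploidy,
        alleles=alleles.astype(np.int64),
    )
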