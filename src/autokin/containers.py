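"""Shared in-memory containers.

The toolkit passes a small number of typed arrays between modules:

* :class:`RelationshipMatrix` — symmetric individuals x individuals
  relatedness values, whether expected (pedigree), realized (tracked
  simulation) or estimated (markers).
* :class:`InbreedingVector` — per-individual inbreeding ``F`` and gamete
  inbreeding ``gamma`` from the pedigree recursion.
* :class:`DosageMatrix` — biallelic marker codings 0..2v used by the
  dosage-based estimators.
* :class:`MultiallelicGenotypes` — per-locus allele multisets used by the
  similarity-index estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "RelationshipMatrix",
    "InbreedingVector",
    "DosageMatrix",
    "MultiallelicGenotypes",
    "MISSING_ALLELE",
]

#: Sentinel allele code marking a missing multiallelic genotype call.
MISSING_ALLELE = -1


@dataclass
class RelationshipMatrix:
    """Symmetric pairwise relatedness values ``r`` (unitless).

    Parameters
    ----------
    ids
        Individual identifiers, in matrix row/column order.
    values
        ``(n, n)`` float array; ``values[i, j]`` is the relatedness between
        individuals ``ids[i]`` and ``ids[j]``.  ``NaN`` marks pairs for which
        an estimator is undefined.
    meta
        Free-form provenance (estimator name, effective locus counts, ...).
    """

    ids: list[str]
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )
        if len(set(self.ids)) != n:
            raise ValueError("duplicate ids in relationship matrix")
        finite = np.isfinite(self.values)
        sym = finite & finite.T
        if not np.allclose(
            self.values[sym], self.values.T[sym], atol=1e-9, equal_nan=True
        ):
            raise ValueError("relationship matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index(self, ind: str) -> int:
        return self.ids.index(ind)

    def get(self, a: str, b: str) -> float:
        """Relatedness between two named individuals."""
        return float(self.values[self.index(a), self.index(b)])

    def offdiag_pairs(self) -> tuple[list[tuple[str, str]], np.ndarray]:
        """All unordered off-diagonal pairs and their values.

        Self pairs are excluded; order follows the upper triangle row-major.
        """
        iu = np.triu_indices(self.n, k=1)
        pairs = [(self.ids[i], self.ids[j]) for i, j in zip(*iu)]
        return pairs, self.values[iu]

    def to_long(self):
        """Long-format DataFrame (id1, id2, r) over the upper triangle."""
        import pandas as pd

        pairs, vals = self.offdiag_pairs()
        return pd.DataFrame(
            {
                "id1": [p[0] for p in pairs],
                "id2": [p[1] for p in pairs],
                "r": vals,
            }
        )


@dataclass
class InbreedingVector:
    """Per-individual inbreeding coefficients from the pedigree recursion.

    ``F[i]`` is the probability that two alleles drawn without replacement
    from individual ``ids[i]`` are identical-by-descent.  ``gamma[i]`` is the
    corresponding probability for two alleles within one gamete produced by
    that individual, ``gamma = alpha + (1 - alpha) * F`` for gametic ploidy
    v >= 2 (``alpha`` being the double-reduction fraction); it is unused for
    diploids.
    """

    ids: list[str]
    F: np.ndarray
    gamma: np.ndarray

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if not (len(self.ids) == self.F.size == self.gamma.size):
            raise ValueError("ids/F/gamma length mismatch")

    def get(self, ind: str) -> float:
        return float(self.F[self.ids.index(ind)])


def _check_ploidy(ploidy: int) -> int:
    ploidy = int(ploidy)
    if ploidy < 2 or ploidy % 2:
        raise ValueError(f"somatic ploidy must be even and >= 2, got {ploidy}")
    return ploidy


@dataclass
class DosageMatrix:
    """Biallelic dosage codings, individuals x loci.

    ``values[i, l]`` counts copies of the reference allele (0..2v) carried by
    individual ``i`` at locus ``l``; ``NaN`` marks a missing call.
    """

    ids: list[str]
    loci: list[str]
    ploidy: int  # somatic, = 2v
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ploidy = _check_ploidy(self.ploidy)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.loci)):
            raise ValueError("dosage shape does not match ids x loci")
        obs = self.values[np.isfinite(self.values)]
        if obs.size and (obs.min() < 0 or obs.max() > self.ploidy):
            raise ValueError(f"dosages outside 0..{self.ploidy}")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def allele_frequencies(self) -> np.ndarray:
        """Reference-allele frequency per locus, p = mean(dosage) / 2v."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.values, axis=0) / self.ploidy

    def polymorphic_mask(self) -> np.ndarray:
        """Boolean mask of loci with within-sample dosage variance > 0."""
        with np.errstate(invalid="ignore"):
            v = np.nanvar(self.values, axis=0)
        return np.nan_to_num(v) > 0


@dataclass
class MultiallelicGenotypes:
    """Unphased multiallelic genotypes, individuals x loci allele multisets.

    ``alleles[i, :, l]`` holds the 2v (unordered) allele codes of individual
    ``i`` at locus ``l``; codes are positive integers, ``MISSING_ALLELE``
    marks an entirely missing call (all 2v slots).
    """

    ids: list[str]
    loci: list[str]
    ploidy: int  # somatic, = 2v
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.ploidy = _check_ploidy(self.ploidy)
        self.alleles = np.asarray(self.alleles)
        exp = (len(self.ids), self.ploidy, len(self.loci))
        if self.alleles.shape != exp:
            raise ValueError(
                f"allele array shape {self.alleles.shape}, expected {exp}"
            )

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_mask(self) -> np.ndarray:
        """(n, L) boolean mask of missing genotype calls."""
        return (self.alleles == MISSING_ALLELE).any(axis=1)

    def locus_alleles(self, l: int) -> np.ndarray:
        """Sorted distinct observed allele codes at locus ``l``."""
        a = self.alleles[:, :, l]
        return np.unique(a[a != MISSING_ALLELE])

    def subset_loci(self, idx: Sequence[int]) -> "MultiallelicGenotypes":
        idx = np.asarray(idx, dtype=int)
        return MultiallelicGenotypes(
            ids=list(self.ids),
            loci=[self.loci[i] for i in idx],
            ploidy=self.ploidy,
            alleles=self.alleles[:, :, idx],
        )
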