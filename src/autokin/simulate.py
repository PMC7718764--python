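"""Polysomic meiosis simulation and pedigree gene dropping.

The simulator tracks founder-allele origin: every founder homolog gets a
globally unique integer label, and descendants are mosaics of those labels.
Identity-by-state of labels is therefore identity-by-descent, which makes a
gene-dropped population an exact ground truth for realized relatedness.

Meiosis model
-------------
Per chromosome, in *bivalent* mode the 2v homologs are partitioned uniformly
at random into v pairs; each bivalent emits one chromatid built as a mosaic
walk that starts on a random member and switches to its partner at crossover
points drawn as a Poisson process at 1 event per Morgan (Haldane model, no
interference, no obligate chiasma).  The gamete is one chromatid per
bivalent, i.e. v homologs.

In *quadrivalent* mode, with probability ``quadrivalent_prob`` four randomly
chosen homologs form a cross-shaped quadrivalent: they are arranged in a
random ring, pairing partners are ring-adjacent and switch at a single
exchange point drawn uniformly on the chromosome.  Two of the four
centromeres are sampled without replacement and each emits one mosaic
chromatid under the position-dependent pairing; the remaining homologs form
bivalents.  Double reduction emerges mechanically when both chromatids carry
a segment of the same parental homolog at a locus — it is never injected as
a rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .genome import GenomeMap
from .pedigree import PedigreeTable

__all__ = [
    "BIVALENT",
    "QUADRIVALENT",
    "DEFAULT_QUADRIVALENT_PROB",
    "MeiosisConfig",
    "TrackedPopulation",
    "Gamete",
    "make_founders",
    "meiosis",
    "gene_drop",
]

BIVALENT = "bivalent_only"
QUADRIVALENT = "quadrivalent"

#: Quadrivalent formation probability per chromosome under natural pairing,
#: by somatic ploidy (random assortment of chromosome ends).
DEFAULT_QUADRIVALENT_PROB = {4: 2 / 3, 6: 9 / 10, 8: 24 / 25}


@dataclass
class MeiosisConfig:
    """Ploidy and meiotic-pairing settings.

    Parameters
    ----------
    ploidy
        Somatic ploidy 2v (even, >= 2).
    pairing
        ``"bivalent_only"`` or ``"quadrivalent"``; quadrivalents are
        illegal for diploids.
    quadrivalent_prob
        Per-chromosome probability of forming one quadrivalent in
        quadrivalent mode.  Defaults to 2/3 (4x), 9/10 (6x), 24/25 (8x).
    centromere_cm
        Centromere position (cM), shared by all chromosomes; chromatid
        walks start here.  Double-reduction magnitude grows with distance
        from the centromere.
    crossover_rate
        Crossover events per Morgan along a chromatid (Haldane: 1).
    """

    ploidy: int
    pairing: str = BIVALENT
    quadrivalent_prob: float | None = None
    centromere_cm: float = 0.0
    crossover_rate: float = 1.0

    def __post_init__(self) -> None:
        self.ploidy = int(self.ploidy)
        if self.ploidy < 2 or self.ploidy % 2:
            raise ValueError("somatic ploidy must be even and >= 2")
        if self.pairing not in (BIVALENT, QUADRIVALENT):
            raise ValueError(f"unknown pairing mode {self.pairing!r}")
        if self.pairing == QUADRIVALENT and self.ploidy == 2:
            raise ValueError("quadrivalent pairing is illegal for diploids")
        if self.quadrivalent_prob is None:
            self.quadrivalent_prob = DEFAULT_QUADRIVALENT_PROB.get(
                self.ploidy, 0.0
            )
        if not 0.0 <= self.quadrivalent_prob <= 1.0:
            raise ValueError("quadrivalent_prob must be in [0, 1]")

    @property
    def v(self) -> int:
        """Gametic ploidy."""
        return self.ploidy // 2


@dataclass
class TrackedPopulation:
    """Gene-dropped individuals with founder-origin allele labels.

    ``alleles[i, h, l]`` is the founder-homolog label carried by homolog
    ``h`` of individual ``i`` at global locus ``l``.  Labels are integers in
    ``range(n_labels)``; label ``f * 2v + h`` traces to homolog ``h`` of
    founder ``origins[f]`` (which may be a virtual founder standing in for
    an unknown parent).
    """

    ids: list[str]
    ploidy: int  # somatic, = 2v
    genome: GenomeMap
    alleles: np.ndarray  # (n, 2v, L) int32
    origins: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        exp = (len(self.ids), self.ploidy, self.genome.n_loci)
        if self.alleles.shape != exp:
            raise ValueError(
                f"allele array shape {self.alleles.shape}, expected {exp}"
            )

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_labels(self) -> int:
        return len(self.origins) * self.ploidy

    def index(self, ind: str) -> int:
        return self.ids.index(ind)

    def genotype(self, ind: str, locus: int) -> np.ndarray:
        """Allele multiset (length 2v) of one individual at one locus."""
        return self.alleles[self.index(ind), :, locus].copy()

    def label_counts(self) -> np.ndarray:
        """(n, n_labels, L) per-locus label count tensor (uint8)."""
        n, _, L = self.alleles.shape
        counts = np.zeros((n, self.n_labels, L), dtype=np.uint8)
        ii = np.arange(L)
        for i in range(n):
            for h in range(self.ploidy):
                np.add.at(counts[i], (self.alleles[i, h], ii), 1)
        return counts


@dataclass
class Gamete:
    """One meiotic product: v homolog label sequences over the genome."""

    ploidy: int  # gametic, = v
    genome: GenomeMap
    alleles: np.ndarray  # (v, L) int32


def _walk_sources(
    xpos: np.ndarray,
    start: int,
    partner_at: Callable[[int, float], int],
    centromere: float,
) -> np.ndarray:
    """Homolog source per segment of a mosaic chromatid.

    Segments are delimited by the sorted crossover positions ``xpos``;
    the walk starts on ``start`` in the segment containing the centromere
    and switches to the position-dependent pairing partner at each
    crossover boundary, in both directions.
    """
    n_seg = xpos.size + 1
    src = np.empty(n_seg, dtype=np.int64)
    k0 = int(np.searchsorted(xpos, centromere, side="right"))
    src[k0] = cur = start
    for k in range(k0 + 1, n_seg):
        cur = partner_at(cur, float(xpos[k - 1]))
        src[k] = cur
    cur = start
    for k in range(k0 - 1, -1, -1):
        cur = partner_at(cur, float(xpos[k]))
        src[k] = cur
    return src


def _crossovers(length_cm: float, rate: float, rng) -> np.ndarray:
    n = rng.poisson(rate * length_cm / 100.0)
    return np.sort(rng.uniform(0.0, length_cm, size=n))


def _bivalent_chromatid(
    H: np.ndarray,
    members: Sequence[int],
    pos: np.ndarray,
    length: float,
    cfg: MeiosisConfig,
    rng,
) -> np.ndarray:
    a, b = int(members[0]), int(members[1])
    start = a if rng.integers(2) == 0 else b
    xpos = _crossovers(length, cfg.crossover_rate, rng)
    src = _walk_sources(
        xpos, start, lambda cur, t: b if cur == a else a, cfg.centromere_cm
    )
    seg = np.searchsorted(xpos, pos, side="right")
    return H[src[seg], np.arange(pos.size)]


def _quadrivalent_chromatids(
    H: np.ndarray,
    ring: np.ndarray,
    pos: np.ndarray,
    length: float,
    cfg: MeiosisConfig,
    rng,
) -> list[np.ndarray]:
    """Two chromatids emitted by one quadrivalent.

    ``ring`` holds 4 homolog indices in random ring order; ring-adjacent
    homologs pair (0-1, 2-3) left of the exchange point and (1-2, 3-0)
    right of it.
    """
    exchange = rng.uniform(0.0, length)
    ring_pos = {int(h): k for k, h in enumerate(ring)}

    def partner_at(cur: int, t: float) -> int:
        k = ring_pos[cur]
        mate = (k ^ 1) if t < exchange else (3 - k)
        return int(ring[mate])

    starts = rng.choice(4, size=2, replace=False)
    out = []
    for s in starts:
        xpos = _crossovers(length, cfg.crossover_rate, rng)
        src = _walk_sources(
            xpos, int(ring[s]), partner_at, cfg.centromere_cm
        )
        seg = np.searchsorted(xpos, pos, side="right")
        out.append(H[src[seg], np.arange(pos.size)])
    return out


def _meiosis_chrom(
    H: np.ndarray,
    pos: np.ndarray,
    length: float,
    cfg: MeiosisConfig,
    rng,
) -> np.ndarray:
    """Gamete homologs (v, L_c) for one chromosome of one parent."""
    two_v = cfg.ploidy
    chromatids: list[np.ndarray] = []
    homologs = rng.permutation(two_v)
    if (
        cfg.pairing == QUADRIVALENT
        and two_v >= 4
        and rng.random() < cfg.quadrivalent_prob
    ):
        ring, rest = homologs[:4], homologs[4:]
        chromatids.extend(
            _quadrivalent_chromatids(H, ring, pos, length, cfg, rng)
        )
    else:
        rest = homologs
    for k in range(0, rest.size, 2):
        chromatids.append(
            _bivalent_chromatid(H, rest[k : k + 2], pos, length, cfg, rng)
        )
    return np.stack(chromatids)


def _meiosis_array(
    parent: np.ndarray, gm: GenomeMap, cfg: MeiosisConfig, rng
) -> np.ndarray:
    """Simulate one meiosis of a (2v, L) parent; returns (v, L)."""
    out = np.empty((cfg.v, gm.n_loci), dtype=parent.dtype)
    for c in range(gm.n_chrom):
        sl = gm.chrom_slice(c)
        out[:, sl] = _meiosis_chrom(
            parent[:, sl], gm.positions[c], gm.lengths[c], cfg, rng
        )
    return out


def meiosis(
    pop: TrackedPopulation, parent: str, cfg: MeiosisConfig, rng
) -> Gamete:
    """Draw one gamete from a tracked individual.

    ``rng`` must be a seeded :class:`numpy.random.Generator`; all
    stochastic entry points take explicit randomness.
    """
    if rng is None:
        raise ValueError("meiosis requires an explicit seeded rng")
    if cfg.ploidy != pop.ploidy:
        raise ValueError(
            f"config ploidy {cfg.ploidy} != population ploidy {pop.ploidy}"
        )
    arr = _meiosis_array(
        pop.alleles[pop.index(parent)], pop.genome, cfg, rng
    )
    return Gamete(ploidy=cfg.v, genome=pop.genome, alleles=arr)


def make_founders(
    ped: PedigreeTable, gm: GenomeMap, cfg: MeiosisConfig
) -> TrackedPopulation:
    """Founder population with globally unique constant homolog labels.

    Founder ``f`` (in pedigree founder order) carries label ``f * 2v + h``
    along the whole of homolog ``h``; founders are thus unrelated with
    unique alleles.
    """
    founders = ped.founders
    two_v = cfg.ploidy
    n = len(founders)
    alleles = np.empty((n, two_v, gm.n_loci), dtype=np.int32)
    for f in range(n):
        for h in range(two_v):
            alleles[f, h, :] = f * two_v + h
    return TrackedPopulation(
        ids=list(founders),
        ploidy=two_v,
        genome=gm,
        alleles=alleles,
        origins=list(founders),
    )


def gene_drop(
    ped: PedigreeTable,
    gm: GenomeMap,
    cfg: MeiosisConfig,
    seed: int | np.random.Generator,
) -> TrackedPopulation:
    """Drop founder alleles through a pedigree by simulated meiosis.

    Founders come from :func:`make_founders`.  Every non-founder is the
    union of one gamete per parent; an unknown parent contributes a gamete
    drawn from a fresh virtual founder with its own unique labels (so
    half-known individuals stay unrelated to the rest through that side).
    Deterministic given the seed.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    two_v = cfg.ploidy
    founders = make_founders(ped, gm, cfg)
    origins = list(founders.origins)
    n = len(ped)
    alleles = np.empty((n, two_v, gm.n_loci), dtype=np.int32)
    index: dict[str, int] = {}
    for i, rec in enumerate(ped.records):
        index[rec.id] = i
        if rec.is_founder:
            alleles[i] = founders.alleles[founders.index(rec.id)]
            continue
        gametes = []
        for slot, parent in enumerate((rec.parent1, rec.parent2)):
            if parent is None:
                base = len(origins) * two_v
                origins.append(f"_virtual_{rec.id}_{slot + 1}")
                virtual = np.empty((two_v, gm.n_loci), dtype=np.int32)
                for h in range(two_v):
                    virtual[h, :] = base + h
                gametes.append(_meiosis_array(virtual, gm, cfg, rng))
            else:
                gametes.append(
                    _meiosis_array(alleles[index[parent]], gm, cfg, rng)
                )
        alleles[i] = np.concatenate(gametes, axis=0)
    return TrackedPopulation(
        ids=ped.ids,
        ploidy=two_v,
        genome=gm,
        alleles=alleles,
        origins=origins,
    )
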