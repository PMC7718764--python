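"""Expected (pedigree) relatedness for autopolyploids.

For an autopolyploid with gametic ploidy ``v`` (somatic allele count 2v per
locus), the coefficient of relationship is ``r_XY = 2v * theta_XY`` where
``theta`` is the coefficient of kinship: the probability that one allele
drawn at random from X is identical-by-descent (IBD) to one drawn at random
from Y.  Relatedness propagates down a pedigree recursively: the relatedness
between X and an offspring O of parents P and Q is half the sum of the
relatedness between X and each parent,

    r_XO = (r_XP + r_XQ) / 2.

Self-relatedness carries the inbreeding coefficient, r_XX = 1 + (2v - 1) F_X.
Unlike diploids, an autopolyploid gamete transmits v alleles, so a parent can
pass *sets* of IBD alleles to one offspring; the inbreeding of offspring O of
P and Q is

    F_O = [C(v,2) (gamma_P + gamma_Q) + v^2 theta_PQ] / C(2v, 2)

where ``gamma = alpha + (1 - alpha) F`` is the probability that two alleles
within one gamete are IBD and ``alpha`` is the double-reduction fraction
(the chance a gamete receives two copies of the same parental homolog
segment through multivalent pairing).  Double reduction therefore only
enters through the gamete term; founders are taken as non-inbred,
unrelated, and carrying unique alleles.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import InbreedingVector, RelationshipMatrix

__all__ = [
    "UNKNOWN",
    "PedigreeRecord",
    "PedigreeTable",
    "PloidyConfig",
    "PedigreeError",
    "read_pedigree",
    "pedigree_from_tuples",
    "expected_relatedness",
    "common_relationships",
]

#: Token denoting an unknown parent in pedigree files.
UNKNOWN = "0"

_HEADER_TOKENS = {"id", "ind", "individual", "name", "genotype"}


class PedigreeError(ValueError):
    """Malformed pedigree input (duplicates, undefined parents, cycles)."""


@dataclass(frozen=True)
class PedigreeRecord:
    """One parentage record; ``None`` marks an unknown parent."""

    id: str
    parent1: str | None
    parent2: str | None

    @property
    def is_founder(self) -> bool:
        return self.parent1 is None and self.parent2 is None


@dataclass
class PedigreeTable:
    """Topologically ordered parentage records.

    Invariants: ids are unique and every named parent occurs earlier in
    ``records``.  Unknown parents are treated downstream as unique,
    non-inbred, unrelated virtual founders.
    """

    records: list[PedigreeRecord]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise PedigreeError(f"duplicate id {rec.id!r}")
            for p in (rec.parent1, rec.parent2):
                if p is not None and p not in seen:
                    raise PedigreeError(
                        f"parent {p!r} of {rec.id!r} does not precede it"
                    )
            seen.add(rec.id)

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    @property
    def founders(self) -> list[str]:
        return [rec.id for rec in self.records if rec.is_founder]

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PedigreeTable):
            return NotImplemented
        return self.records == other.records


@dataclass
class PloidyConfig:
    """Ploidy and double-reduction settings for the expected-relatedness
    recursion.

    Parameters
    ----------
    v
        Gametic ploidy (diploid v=1, autotetraploid v=2, ...).  The somatic
        allele count per locus is 2v.
    alpha
        Double-reduction fraction in [0, 1].  Forced to 0 for diploids,
        where a gamete carries a single allele and double reduction cannot
        occur.
    """

    v: int
    alpha: float = 0.0

    def __post_init__(self) -> None:
        self.v = int(self.v)
        if self.v < 1:
            raise ValueError("gametic ploidy v must be >= 1")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("double-reduction alpha must be in [0, 1]")
        if self.v == 1:
            self.alpha = 0.0

    @property
    def somatic(self) -> int:
        return 2 * self.v


def _parse_parent(token: object) -> str | None:
    s = "" if token is None else str(token).strip()
    if s in ("", UNKNOWN) or s.lower() == "na":
        return None
    return s


def _toposort(rows: list[tuple[str, str | None, str | None]]) -> PedigreeTable:
    """Canonical topological ordering: generation depth, then id.

    The canonical key makes the result invariant to the row order of the
    input file (the same pedigree shuffled parses to the same table).
    """
    ids = [r[0] for r in rows]
    for i, name in enumerate(ids):
        if name in ids[:i]:
            raise PedigreeError(f"duplicate id {name!r} (row {i + 1})")
    known = set(ids)
    parents = {r[0]: tuple(p for p in r[1:] if p is not None) for r in rows}
    for i, r in enumerate(rows):
        for p in parents[r[0]]:
            if p not in known:
                raise PedigreeError(
                    f"row {i + 1}: parent {p!r} of {r[0]!r} is never defined "
                    f"and not marked unknown ({UNKNOWN!r})"
                )

    depth: dict[str, int] = {}

    def _depth(name: str, stack: tuple[str, ...]) -> int:
        if name in stack:
            cyc = stack[stack.index(name):] + (name,)
            raise PedigreeError("pedigree cycle: " + " -> ".join(cyc))
        if name not in depth:
            ps = parents[name]
            depth[name] = (
                0 if not ps else 1 + max(_depth(p, stack + (name,)) for p in ps)
            )
        return depth[name]

    for name in ids:
        _depth(name, ())

    by_id = {r[0]: r for r in rows}
    order = sorted(ids, key=lambda n: (depth[n], n))
    return PedigreeTable(
        [PedigreeRecord(*by_id[name]) for name in order]
    )


def pedigree_from_tuples(
    rows: Iterable[tuple[str, str | None, str | None]]
) -> PedigreeTable:
    """Build a sorted :class:`PedigreeTable` from (id, parent1, parent2)
    tuples; parents may be ``None`` or the ``"0"`` token."""
    norm = [
        (str(i).strip(), _parse_parent(p1), _parse_parent(p2))
        for i, p1, p2 in rows
    ]
    return _toposort(norm)


def read_pedigree(path) -> PedigreeTable:
    """Read a pedigree CSV (columns id, parent1, parent2; header optional).

    ``"0"``, empty, or ``NA`` denote an unknown parent.  Rows may appear in
    any order; the returned table is canonically sorted with parents before
    offspring.  Duplicate ids, undefined parents, and cycles are rejected
    with informative errors.
    """
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    df = pd.read_csv(
        io.StringIO(text), header=None, dtype=str, skip_blank_lines=True
    )
    if df.shape[1] < 3:
        raise PedigreeError(
            f"pedigree file needs 3 columns (id,parent1,parent2), "
            f"found {df.shape[1]}"
        )
    df = df.iloc[:, :3]
    first = str(df.iloc[0, 0]).strip().lower()
    if first in _HEADER_TOKENS:
        df = df.iloc[1:]
    rows = [
        (str(r[0]).strip(), r[1], r[2])
        for r in df.itertuples(index=False, name=None)
    ]
    return pedigree_from_tuples(rows)


def write_pedigree(ped: PedigreeTable, path) -> None:
    """Write a pedigree table back to CSV with a header row."""
    df = pd.DataFrame(
        [
            (r.id, r.parent1 or UNKNOWN, r.parent2 or UNKNOWN)
            for r in ped.records
        ],
        columns=["id", "parent1", "parent2"],
    )
    df.to_csv(path, index=False)


def expected_relatedness(
    ped: PedigreeTable,
    cfg: PloidyConfig,
    *,
    return_kinship: bool = False,
) -> tuple[RelationshipMatrix, InbreedingVector]:
    """Expected pairwise relatedness and inbreeding from a pedigree.

    Runs the kinship recursion in pedigree order.  Founders (both parents
    unknown) are non-inbred with ``theta_XX = 1/(2v)``; an unknown parent of
    a non-founder is a fresh virtual founder contributing ``theta = 0`` and
    gamete inbreeding ``gamma = alpha``.

    Parameters
    ----------
    ped
        Topologically sorted pedigree.
    cfg
        Gametic ploidy and double-reduction fraction.
    return_kinship
        If true, return the kinship matrix ``theta`` instead of
        ``r = 2v * theta`` (the inbreeding vector is unchanged).

    Returns
    -------
    (RelationshipMatrix, InbreedingVector)
    """
    v = cfg.v
    alpha = cfg.alpha
    n = len(ped)
    ids = ped.ids
    idx = {name: i for i, name in enumerate(ids)}
    theta = np.zeros((n, n))
    F = np.zeros(n)
    gamma = np.zeros(n)

    c_v2 = math.comb(v, 2)
    c_2v2 = math.comb(2 * v, 2)

    def _theta_col(p: str | None, o: int) -> np.ndarray:
        # kinship of every earlier individual with parent p (0 if unknown)
        if p is None:
            return np.zeros(o)
        return theta[:o, idx[p]]

    for o, rec in enumerate(ped.records):
        if rec.is_founder:
            F[o] = 0.0
        else:
            g = [
                gamma[idx[p]] if p is not None else alpha
                for p in (rec.parent1, rec.parent2)
            ]
            if rec.parent1 is not None and rec.parent2 is not None:
                th_pq = theta[idx[rec.parent1], idx[rec.parent2]]
            else:
                th_pq = 0.0  # any unknown parent is unrelated to everyone
            F[o] = (c_v2 * (g[0] + g[1]) + v * v * th_pq) / c_2v2
            col = 0.5 * (
                _theta_col(rec.parent1, o) + _theta_col(rec.parent2, o)
            )
            theta[:o, o] = col
            theta[o, :o] = col
        gamma[o] = alpha + (1.0 - alpha) * F[o]
        theta[o, o] = (1.0 + (2 * v - 1) * F[o]) / (2 * v)

    values = theta if return_kinship else 2 * v * theta
    rm = RelationshipMatrix(
        ids=list(ids),
        values=values,
        meta={"v": v, "alpha": alpha, "scale": "theta" if return_kinship else "r"},
    )
    return rm, InbreedingVector(ids=list(ids), F=F, gamma=gamma)


#: Fixture pedigree covering the textbook relationship classes.
_COMMON_ROWS: tuple[tuple[str, str, str], ...] = (
    ("GP1", "0", "0"),
    ("GP2", "0", "0"),
    ("GP3", "0", "0"),
    ("GP4", "0", "0"),
    ("GP5", "0", "0"),
    ("GP6", "0", "0"),
    ("A", "GP1", "GP2"),
    ("B", "GP1", "GP2"),
    ("C", "GP1", "GP3"),
    ("D", "GP4", "GP5"),
    ("E", "A", "D"),
    ("F", "E", "GP6"),
)

_COMMON_PAIRS: tuple[tuple[str, str, str], ...] = (
    ("parent_offspring", "A", "E"),
    ("full_sibs", "A", "B"),
    ("half_sibs", "A", "C"),
    ("uncle_nephew", "B", "E"),
    ("grandparent_grandoffspring", "A", "F"),
    ("granduncle_grandnephew", "B", "F"),
    ("unrelated", "A", "D"),
    ("unrelated_founders", "GP1", "GP4"),
)


def common_relationships(
    v: int = 2,
) -> tuple[PedigreeTable, pd.DataFrame]:
    """Fixture pedigree with one labelled pair per common relationship.

    Covers parent-offspring, full sibs, half sibs, (full) uncle-nephew,
    grandparent-grandoffspring, granduncle-grandnephew, plus unrelated
    check pairs.  Expected relatedness is computed by the pedigree
    recursion at double reduction alpha = 0 (it is the same for every
    gametic ploidy because all individuals involved are non-inbred).

    Returns
    -------
    (PedigreeTable, DataFrame)
        The pedigree and a table with columns
        ``relationship, id1, id2, expected_r``.
    """
    ped = pedigree_from_tuples(_COMMON_ROWS)
    rm, _ = expected_relatedness(ped, PloidyConfig(v=v, alpha=0.0))
    rows = [
        (label, a, b, rm.get(a, b)) for label, a, b in _COMMON_PAIRS
    ]
    table = pd.DataFrame(
        rows, columns=["relationship", "id1", "id2", "expected_r"]
    )
    return ped, table
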