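"""Realized (observed) identical-by-descent relatedness.

For tracked simulations, allele labels are founder origins, so
identity-by-state of labels *is* identity-by-descent.  At one locus a pair
of 2v-allele genotypes shares exactly ``i`` alleles IBD, where ``i`` is the
multiset intersection of the two label multisets; the per-locus relatedness
contribution is ``i / (2v)`` and the realized relatedness is its average
over loci:

    r_obs(X, Y) = (1/L) sum_j i_j / (2v).

This is the ground truth against which the marker-based estimators are
scored.
"""

from __future__ import annotations

from collections import Counter
from typing import Sequence

import numpy as np

from .containers import RelationshipMatrix
from .simulate import TrackedPopulation

__all__ = [
    "shared_allele_count",
    "delta_at_locus",
    "realized_matrix",
    "realized_pair",
]


def shared_allele_count(x: Sequence[int], y: Sequence[int]) -> int:
    """Multiset intersection size of two equal-size allele multisets."""
    x = list(x)
    y = list(y)
    if len(x) != len(y):
        raise ValueError(
            f"allele multisets differ in size ({len(x)} vs {len(y)})"
        )
    cx, cy = Counter(x), Counter(y)
    return sum(min(c, cy[a]) for a, c in cx.items())


def delta_at_locus(x: Sequence[int], y: Sequence[int]) -> np.ndarray:
    """Indicator Delta-vector for one locus.

    Returns a length 2v+1 array with ``Delta[i] = 1`` where ``i`` is the
    number of alleles shared between the two multisets (for tracked data
    each Delta is an indicator, 0 or 1).
    """
    i = shared_allele_count(x, y)
    delta = np.zeros(len(list(x)) + 1)
    delta[i] = 1.0
    return delta


def _pair_r(cx: np.ndarray, cy: np.ndarray, two_v: int) -> float:
    # cx, cy: (n_labels, L_sel) per-locus label counts
    shared = np.minimum(cx, cy).sum(dtype=np.int64)
    return float(shared) / (two_v * cx.shape[1])


def realized_matrix(
    pop: TrackedPopulation, loci: Sequence[int] | None = None
) -> RelationshipMatrix:
    """Realized relatedness matrix of a tracked population.

    Parameters
    ----------
    pop
        Gene-dropped population with founder-origin labels.
    loci
        Optional global locus indices to average over (defaults to all
        loci).  Estimator benchmarks must pass the same subset they hand
        to the estimator.
    """
    if loci is None:
        sel = np.arange(pop.genome.n_loci)
    else:
        sel = np.asarray(list(loci), dtype=int)
    if sel.size == 0:
        raise ValueError("realized_matrix needs at least one locus")
    counts = pop.label_counts()[:, :, sel]
    n = pop.n
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = _pair_r(
                counts[i], counts[j], pop.ploidy
            )
    return RelationshipMatrix(
        ids=list(pop.ids),
        values=values,
        meta={"kind": "realized_ibd", "n_loci": int(sel.size)},
    )


def realized_pair(
    pop: TrackedPopulation,
    a: str,
    b: str,
    loci: Sequence[int] | None = None,
) -> float:
    """Realized relatedness for a single named pair (cheaper than the full
    matrix for replicated summaries)."""
    if loci is None:
        sel = slice(None)
        n_loci = pop.genome.n_loci
    else:
        sel = np.asarray(list(loci), dtype=int)
        n_loci = sel.size
    ia, ib = pop.index(a), pop.index(b)
    xa = pop.alleles[ia][:, sel]
    xb = pop.alleles[ib][:, sel]
    # per-locus multiset intersection via a vectorized sort-merge along the
    # (small) homolog axis; avoids building the full label-count tensor
    sa = np.sort(xa, axis=0)
    sb = np.sort(xb, axis=0)
    two_v = pop.ploidy
    ptr_shared = np.zeros(n_loci, dtype=np.int64)
    # merge counts label-by-label: for each locus, intersection of sorted
    # arrays.  Loop over the (small) homolog axis, not loci.
    ia_ptr = np.zeros(n_loci, dtype=np.int64)
    ib_ptr = np.zeros(n_loci, dtype=np.int64)
    for _ in range(2 * two_v):
        active = (ia_ptr < two_v) & (ib_ptr < two_v)
        if not active.any():
            break
        av = sa[np.minimum(ia_ptr, two_v - 1), np.arange(n_loci)]
        bv = sb[np.minimum(ib_ptr, two_v - 1), np.arange(n_loci)]
        eq = active & (av == bv)
        lt = active & (av < bv)
        gt = active & (av > bv)
        ptr_shared += eq
        ia_ptr += eq | lt
        ib_ptr += eq | gt
    shared = int(ptr_shared.sum())
    return shared / (two_v * n_loci)
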