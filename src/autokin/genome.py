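"""Genetic map construction.

A :class:`GenomeMap` is a set of chromosomes with lengths in centiMorgans
and ordered locus positions on each.  The default build emulates a dense,
evenly spaced map: 10 chromosomes of 100 cM with one locus every 0.1 cM,
10,000 loci in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenomeMap", "build_genome"]


@dataclass(frozen=True)
class GenomeMap:
    """Chromosome lengths (cM) and per-chromosome locus positions (cM).

    Positions must be strictly increasing within [0, length] on each
    chromosome.  Loci are addressed globally by concatenating chromosomes
    in order; ``offsets`` gives the global index of each chromosome's first
    locus.
    """

    names: tuple[str, ...]
    lengths: tuple[float, ...]
    positions: tuple[np.ndarray, ...]
    offsets: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not (len(self.names) == len(self.lengths) == len(self.positions)):
            raise ValueError("names/lengths/positions length mismatch")
        for name, length, pos in zip(self.names, self.lengths, self.positions):
            if length <= 0:
                raise ValueError(f"chromosome {name}: non-positive length")
            if pos.size == 0:
                raise ValueError(f"chromosome {name}: no loci")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"chromosome {name}: positions not increasing")
            if pos[0] < 0 or pos[-1] > length:
                raise ValueError(f"chromosome {name}: positions outside map")
        counts = np.array([p.size for p in self.positions])
        object.__setattr__(
            self, "offsets", np.concatenate(([0], np.cumsum(counts)))
        )

    @property
    def n_chrom(self) -> int:
        return len(self.names)

    @property
    def n_loci(self) -> int:
        return int(self.offsets[-1])

    def chrom_slice(self, c: int) -> slice:
        return slice(int(self.offsets[c]), int(self.offsets[c + 1]))

    def locus_names(self) -> list[str]:
        return [
            f"{name}_{i + 1}"
            for c, name in enumerate(self.names)
            for i in range(self.positions[c].size)
        ]

    def to_frame(self) -> pd.DataFrame:
        """Map as a DataFrame (marker, chromosome, position_cM)."""
        return pd.DataFrame(
            {
                "marker": self.locus_names(),
                "chromosome": [
                    name
                    for c, name in enumerate(self.names)
                    for _ in range(self.positions[c].size)
                ],
                "position_cM": np.concatenate(self.positions),
            }
        )


def build_genome(
    n_chrom: int = 10,
    length_cm: float = 100.0,
    spacing_cm: float = 0.1,
) -> GenomeMap:
    """Evenly spaced genome: loci at spacing, 2*spacing, ..., length.

    ``spacing_cm`` must divide ``length_cm`` exactly so each chromosome
    carries ``length/spacing`` loci (the default yields 10 x 1,000 =
    10,000 loci).
    """
    if n_chrom <= 0 or length_cm <= 0 or spacing_cm <= 0:
        raise ValueError("n_chrom, length_cm and spacing_cm must be positive")
    n = length_cm / spacing_cm
    if abs(n - round(n)) > 1e-9:
        raise ValueError(
            f"spacing {spacing_cm} cM does not divide length {length_cm} cM"
        )
    n = int(round(n))
    pos = spacing_cm * np.arange(1, n + 1)
    return GenomeMap(
        names=tuple(f"chr{i + 1}" for i in range(n_chrom)),
        lengths=tuple(float(length_cm) for _ in range(n_chrom)),
        positions=tuple(pos.copy() for _ in range(n_chrom)),
    )
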