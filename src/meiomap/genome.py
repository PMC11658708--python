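"""Genome model: chromosome sizes, centromeres and length-proportional weights.

The default genome is the 16 nuclear chromosomes of *Saccharomyces
cerevisiae* (R64 assembly sizes, centromere midpoints rounded to the
nearest base).  Chromosome weights ``p_i = L_i / sum(L)`` drive the
length-proportional crossover allocation used by the non-exchange
chromosome simulation and by the synthetic-meiosis generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenomeModel", "yeast_genome"]

# R64 (sacCer3) chromosome lengths in bp.
_SC_LENGTHS = {
    "chr01": 230_218, "chr02": 813_184, "chr03": 316_620, "chr04": 1_531_933,
    "chr05": 576_874, "chr06": 270_161, "chr07": 1_090_940, "chr08": 562_643,
    "chr09": 439_888, "chr10": 745_751, "chr11": 666_816, "chr12": 1_078_177,
    "chr13": 924_431, "chr14": 784_333, "chr15": 1_091_291, "chr16": 948_066,
}

# Approximate centromere midpoints (bp) on the same assembly.
_SC_CENTROMERES = {
    "chr01": 151_465, "chr02": 238_207, "chr03": 114_385, "chr04": 449_711,
    "chr05": 151_987, "chr06": 148_510, "chr07": 497_038, "chr08": 105_703,
    "chr09": 355_629, "chr10": 436_425, "chr11": 440_246, "chr12": 150_947,
    "chr13": 268_031, "chr14": 628_758, "chr15": 326_702, "chr16": 555_957,
}


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome lengths (bp), centromere positions (bp) and derived weights.

    Invariants: every length is positive, every centromere lies within its
    chromosome, and the allocation probabilities sum to 1 (within 1e-12).
    """

    names: tuple[str, ...]
    lengths: tuple[int, ...]
    centromeres: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths must have equal length")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.centromeres:
            if len(self.centromeres) != len(self.lengths):
                raise ValueError("centromeres must match chromosome count")
            for c, l in zip(self.centromeres, self.lengths):
                if not (1 <= c <= l):
                    raise ValueError(f"centromere {c} outside chromosome of length {l}")

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))

    @property
    def probabilities(self) -> np.ndarray:
        """Length-proportional allocation weights p_i = L_i / sum(L)."""
        p = np.asarray(self.lengths, dtype=float)
        return p / p.sum()

    def length_of(self, chrom: str) -> int:
        return self.lengths[self.names.index(chrom)]

    def centromere_of(self, chrom: str) -> int:
        if not self.centromeres:
            raise ValueError("genome model carries no centromere positions")
        return self.centromeres[self.names.index(chrom)]


def yeast_genome() -> GenomeModel:
    """The 16-chromosome *S. cerevisiae* genome model used by default."""
    names = tuple(sorted(_SC_LENGTHS))
    return GenomeModel(
        names=names,
        lengths=tuple(_SC_LENGTHS[n] for n in names),
        centromeres=tuple(_SC_CENTROMERES[n] for n in names),
    )
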