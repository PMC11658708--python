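"""Strand-matrix container shared by the simulator, genotyper and event caller.

A meiosis is represented per chromosome as an 8 x n_markers matrix of binary
parental genotype calls: 1 for the reference parent (S288c-like, "parent A")
and 0 for the variant parent (SK1-like, "parent B").  Rows are ordered as
chromatid pairs: rows ``2k`` and ``2k+1`` are the "mother" and "daughter"
strands of chromatid ``k``; chromatids 0-1 start the chromosome as parent A
and chromatids 2-3 as parent B.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PARENT_A",
    "PARENT_B",
    "HET",
    "MISSING",
    "StrandMatrix",
]

PARENT_A: int = 1   # reference parent (S288c); encoded 1 as in the binary signal
PARENT_B: int = 0   # variant parent (SK1); encoded 0
HET: int = 2        # heteroduplex (mixed-read) call
MISSING: int = -1


@dataclass
class StrandMatrix:
    """8 strands x markers of binary genotype calls for one chromosome.

    ``geno`` holds values in {0, 1, -1}; heteroduplex calls never reach a
    strand matrix (octads discard them, mocktads split them into the two
    strands of the pair).  ``polarity_known[k]`` is False for a mocktad
    spore whose mother/daughter orientation is the arbitrary default and
    has not been phased with a resequenced colony.
    """

    chrom: str
    positions: np.ndarray          # (n,) 1-based bp, strictly increasing
    geno: np.ndarray               # (8, n) int8 in {PARENT_A, PARENT_B, MISSING}
    polarity_known: np.ndarray = field(default=None)  # (4,) bool
    het_mask: np.ndarray = field(default=None)        # (4, n) bool: spore was HET here

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.geno = np.asarray(self.geno, dtype=np.int8)
        if self.geno.shape != (8, self.positions.size):
            raise ValueError(
                f"geno shape {self.geno.shape} does not match "
                f"{self.positions.size} markers"
            )
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("marker positions must be strictly increasing")
        if self.polarity_known is None:
            self.polarity_known = np.ones(4, dtype=bool)
        else:
            self.polarity_known = np.asarray(self.polarity_known, dtype=bool)

    @property
    def n_markers(self) -> int:
        return int(self.positions.size)

    def retained(self) -> np.ndarray:
        """Boolean mask of columns with no MISSING strand (used for segmentation)."""
        return ~np.any(self.geno == MISSING, axis=0)

    def copy(self) -> "StrandMatrix":
        return StrandMatrix(
            chrom=self.chrom,
            positions=self.positions.copy(),
            geno=self.geno.copy(),
            polarity_known=self.polarity_known.copy(),
            het_mask=None if self.het_mask is None else self.het_mask.copy(),
        )
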