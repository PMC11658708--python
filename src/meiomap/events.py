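"""Segregation-pattern segmentation and recombination event calling.

Each retained marker column of a strand matrix shows a segregation
pattern — the ratio of reference-parent to variant-parent alleles over
the eight strands (4:4, 5:3, 6:2, 6:2*, 4:4*, 8:0, ...).  Chromosomes are
split into maximal runs of identical 8-strand genotype vectors
(segments); runs that depart from Mendelian 4:4 segregation, together
with haplotype switch points between Mendelian runs, are grouped into
recombination events whenever they are separated by less than 1.5 kb of
4:4 segregation.  Crossover counts are read from the flanking Mendelian
haplotypes: a crossover is a pair of chromatids whose parental identity
differs between the two flanks.

Events that run into a chromosome end without returning to 4:4 cannot be
classified and are typed "U".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import MISSING, PARENT_A, StrandMatrix

__all__ = [
    "SegPattern",
    "Segment",
    "Segmentation",
    "RecombinationEvent",
    "classify_column",
    "segment_chromosome",
    "count_crossovers",
    "call_events",
]


@dataclass(frozen=True)
class SegPattern:
    """Segregation pattern of one column: countA:countB with a star flag.

    The star marks aberrant strand arrangements: a discordant
    mother/daughter pair (retained heteroduplex) in an even-count column,
    or — when a parental reference configuration is supplied — a 4:4
    column with concordant pairs whose chromatid arrangement differs from
    it.
    """

    n_a: int
    n_b: int
    star: bool
    n_discordant: int

    @property
    def ratio(self) -> str:
        return f"{self.n_a}:{self.n_b}{'*' if self.star else ''}"

    @property
    def is_mendelian(self) -> bool:
        """4:4 with concordant strand pairs (any chromatid arrangement)."""
        return self.n_a == 4 and self.n_discordant == 0

    @property
    def label(self) -> str:
        if self.n_a == 4 and self.n_discordant == 0:
            return "MENDELIAN"
        if self.n_a == 4:
            return "SYMMETRIC"
        if {self.n_a, self.n_b} == {5, 3}:
            return "HALF_CONVERSION"
        if {self.n_a, self.n_b} == {6, 2}:
            return "TRANS" if self.n_discordant else "FULL_CONVERSION"
        return "DOUBLE"   # 7:1, 1:7, 8:0, 0:8

    def __str__(self) -> str:
        return self.ratio


def classify_column(
    col: np.ndarray, parental: np.ndarray | None = None
) -> SegPattern:
    """Pattern of one 8-strand column (no MISSING values allowed)."""
    col = np.asarray(col)
    if np.any(col == MISSING):
        raise ValueError("column contains MISSING strands")
    n_a = int(np.sum(col == PARENT_A))
    pairs = col.reshape(4, 2)
    n_disc = int(np.sum(pairs[:, 0] != pairs[:, 1]))
    star = False
    if n_a % 2 == 0:
        if n_disc > 0:
            star = True
        elif n_a == 4 and parental is not None and not np.array_equal(
            col, np.asarray(parental)
        ):
            star = True
    return SegPattern(n_a=n_a, n_b=8 - n_a, star=star, n_discordant=n_disc)


@dataclass
class Segment:
    """Maximal run of identical strand-genotype vectors."""

    chrom: str
    start_idx: int      # retained-column indices, inclusive
    end_idx: int
    start_pos: int
    end_pos: int
    vector: np.ndarray  # (8,)
    pattern: SegPattern

    @property
    def n_markers(self) -> int:
        return self.end_idx - self.start_idx + 1

    @property
    def extent_bp(self) -> int:
        return self.end_pos - self.start_pos


@dataclass
class Segmentation:
    """Segments of one chromosome plus the retained marker arrays they index."""

    chrom: str
    positions: np.ndarray    # retained marker positions
    geno: np.ndarray         # 8 x retained markers
    segments: list[Segment]


def segment_chromosome(sm: StrandMatrix) -> Segmentation:
    """Split a chromosome into maximal same-vector runs.

    Columns containing MISSING strands are excluded beforehand and do not
    interrupt runs (depth gaps bridge).  The union of segments covers every
    retained marker exactly once.
    """
    keep = sm.retained()
    pos = sm.positions[keep]
    geno = sm.geno[:, keep]
    segments: list[Segment] = []
    n = pos.size
    if n == 0:
        return Segmentation(sm.chrom, pos, geno, segments)
    change = np.flatnonzero(np.any(geno[:, 1:] != geno[:, :-1], axis=0)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change - 1, [n - 1]])
    for s, e in zip(starts, ends):
        vec = geno[:, s].copy()
        segments.append(
            Segment(
                chrom=sm.chrom,
                start_idx=int(s),
                end_idx=int(e),
                start_pos=int(pos[s]),
                end_pos=int(pos[e]),
                vector=vec,
                pattern=classify_column(vec),
            )
        )
    return Segmentation(sm.chrom, pos, geno, segments)


def count_crossovers(
    left_vec: np.ndarray, right_vec: np.ndarray
) -> tuple[int, list[int], bool]:
    """CO count between two Mendelian flanks.

    Returns (co_count, changed chromatids, irregular flag).  A crossover is
    a reciprocal exchange, so the number of chromatids whose parental
    identity changes must be even; an odd number marks the event complex
    and the count is the best even fit (floor of half).
    """
    changed = [k for k in range(4) if left_vec[2 * k] != right_vec[2 * k]]
    irregular = len(changed) % 2 == 1
    return len(changed) // 2, changed, irregular


@dataclass
class RecombinationEvent:
    """A cluster of non-Mendelian segments and/or haplotype switches.

    ``start_idx``/``end_idx`` index the retained markers of the
    segmentation (``start_idx > end_idx`` for a pure switch event with no
    internal markers).  ``nco_runs`` maps non-crossover-involved chromatid
    ids to maximal runs of markers (index pairs, inclusive) at which the
    chromatid departs from its flanking identity.
    """

    chrom: str
    start_idx: int
    end_idx: int
    start_pos: int
    end_pos: int
    segments: list[Segment]
    positions: np.ndarray = field(repr=False)
    geno: np.ndarray = field(repr=False)
    type_u: bool = False
    left_vec: np.ndarray | None = field(default=None, repr=False)
    right_vec: np.ndarray | None = field(default=None, repr=False)
    co_count: int = 0
    changed_chromatids: list[int] = field(default_factory=list)
    complex_flag: bool = False
    nco_count: int = 0
    nco_runs: dict[int, list[tuple[int, int]]] = field(default_factory=dict)
    category: object = None      # filled by meiomap.classify

    @property
    def n_markers(self) -> int:
        return max(0, self.end_idx - self.start_idx + 1)

    @property
    def span_bp(self) -> int:
        return self.end_pos - self.start_pos if self.n_markers else 0

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start_pos + self.end_pos)

    @property
    def left_flank_pos(self) -> int | None:
        i = self.start_idx - 1
        return int(self.positions[i]) if i >= 0 else None

    @property
    def right_flank_pos(self) -> int | None:
        i = self.end_idx + 1
        return int(self.positions[i]) if i < self.positions.size else None

    def pattern_string(self) -> str:
        inner = "|".join(s.pattern.ratio for s in self.segments)
        left = "4:4|" if self.left_vec is not None else ""
        right = "|4:4" if self.right_vec is not None else ""
        return left + inner + right if inner else (left + right).replace("||", "|")

    def chromatid_flank_identity(self, k: int) -> int | None:
        if self.left_vec is None:
            return None
        return int(self.left_vec[2 * k])


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    out = []
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return out
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    for s, e in zip(starts, ends):
        out.append((int(idx[s]), int(idx[e])))
    return out


def call_events(
    segmentation: Segmentation, min_gap_bp: int = 1500
) -> list[RecombinationEvent]:
    """Group anomalies into recombination events.

    Anomalies are (i) non-Mendelian segments and (ii) haplotype switch
    points between two adjacent Mendelian segments with different
    chromatid arrangements (a crossover with no detectable strand
    transfer, or the boundary of a perfectly overlapping double
    conversion).  Consecutive anomalies merge into one event when the 4:4
    interval between their outermost non-Mendelian markers is shorter
    than ``min_gap_bp``; they stay separate when it is at least
    ``min_gap_bp`` ("at least 1.5 kb of 4:4").
    """
    segs = segmentation.segments
    pos = segmentation.positions
    geno = segmentation.geno
    if not segs:
        return []
    mend = [s.pattern.is_mendelian for s in segs]

    # ordered anomaly items: (first_pos, last_pos, start_idx, end_idx, seg_index or None)
    items: list[tuple[float, float, int, int, int | None]] = []
    for i, s in enumerate(segs):
        if not mend[i]:
            items.append((float(s.start_pos), float(s.end_pos), s.start_idx, s.end_idx, i))
        if i + 1 < len(segs) and mend[i] and mend[i + 1]:
            j = s.end_idx
            mid = 0.5 * (pos[j] + pos[j + 1])
            items.append((mid, mid, j + 1, j, None))
    if not items:
        return []

    groups: list[list[tuple]] = [[items[0]]]
    for it in items[1:]:
        prev = groups[-1][-1]
        # separation requires an intervening Mendelian marker run of at
        # least min_gap_bp; adjacent anomalies (no 4:4 marker between)
        # always stay in one event regardless of the bp distance
        adjacent = it[2] <= prev[3] + 1
        if adjacent or it[0] - prev[1] < min_gap_bp:
            groups[-1].append(it)
        else:
            groups.append([it])

    events: list[RecombinationEvent] = []
    for grp in groups:
        start_idx = min(it[2] for it in grp)
        end_idx = max(it[3] for it in grp)
        seg_indices = [it[4] for it in grp if it[4] is not None]
        if seg_indices:
            lo, hi = min(seg_indices), max(seg_indices)
            members = segs[lo:hi + 1]
        else:
            members = []
        if end_idx >= start_idx:
            start_pos, end_pos = int(pos[start_idx]), int(pos[end_idx])
        else:
            start_pos, end_pos = int(pos[end_idx]), int(pos[start_idx])

        # flanking Mendelian segments immediately outside the group
        first_seg = seg_indices[0] if seg_indices else None
        # locate flanks by marker index: segment containing start_idx-1 / end_idx+1
        left_vec = right_vec = None
        li = start_idx - 1
        ri = end_idx + 1 if end_idx >= start_idx else start_idx
        if li >= 0:
            lseg = _segment_at(segs, li)
            if lseg is not None and lseg.pattern.is_mendelian:
                left_vec = lseg.vector
        if ri < pos.size:
            rseg = _segment_at(segs, ri)
            if rseg is not None and rseg.pattern.is_mendelian:
                right_vec = rseg.vector

        ev = RecombinationEvent(
            chrom=segmentation.chrom,
            start_idx=start_idx,
            end_idx=end_idx,
            start_pos=start_pos,
            end_pos=end_pos,
            segments=members,
            positions=pos,
            geno=geno,
            type_u=left_vec is None or right_vec is None,
            left_vec=left_vec,
            right_vec=right_vec,
        )
        if not ev.type_u:
            co, changed, irregular = count_crossovers(left_vec, right_vec)
            ev.co_count = co
            ev.changed_chromatids = changed
            ev.complex_flag = irregular
            if end_idx >= start_idx:
                cols = slice(start_idx, end_idx + 1)
                for k in range(4):
                    if k in changed:
                        continue
                    ident = left_vec[2 * k]
                    diff = (geno[2 * k, cols] != ident) | (geno[2 * k + 1, cols] != ident)
                    runs = _runs(diff)
                    if runs:
                        ev.nco_runs[k] = [(s + start_idx, e + start_idx) for s, e in runs]
            # preliminary NCO count; the classifier may promote double NCOs to 2
            if ev.nco_runs:
                ev.nco_count = 1
        events.append(ev)
    return events


def _segment_at(segs: list[Segment], idx: int) -> Segment | None:
    """Segment containing retained-marker index ``idx`` (binary search)."""
    lo, hi = 0, len(segs) - 1
    while lo <= hi:
        mid = (lo + hi) // 2
        s = segs[mid]
        if idx < s.start_idx:
            hi = mid - 1
        elif idx > s.end_idx:
            lo = mid + 1
        else:
            return s
    return None
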