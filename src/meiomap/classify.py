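"""Event taxonomy: multi-DSB classes, trans-DSB evidence, CO/NCO
strand-transfer subcategories, hotspot overlap and mitotic-artefact QC.

The classification is observational and conservative, mirroring how
octad images are read:

* multi-DSB classes — double COs only when all four chromatids undergo a
  double reciprocal exchange; CO+NCO only when the conversion falls on a
  third chromatid; double NCOs only on two sister chromatids or on two
  homologues with perfectly overlapping tracts;
* trans-DSB evidence — an 8:0/0:8 or 7:1/1:7 segment inside the event
  (8:0 requires an adjacent heteroduplex-bearing segment, since isolated
  8:0 blocks are suspected mitotic/premeiotic conversions);
* CO and NCO subcategories read off the heteroduplex/full-conversion
  tract arrangement; conversion direction is taken from the column
  ratios themselves (a 5:3 column converts toward the five-count
  parent), which keeps the taxonomy computable in unphased mocktads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import RecombinationEvent, Segment, _runs
from .matrix import PARENT_A

__all__ = [
    "EventCategory",
    "HotspotTrack",
    "classify_multi_dsb",
    "detect_trans_dsb",
    "classify_nco",
    "classify_co",
    "classify_event",
    "classify_all",
    "hotspot_overlap",
    "qc_filter",
    "QCReport",
]

MULTI_DSB_CLASSES = ("none", "dCO", "dNCO_sister", "dNCO_overlap", "CO_plus_NCO")
NCO_CLASSES = (
    "none", "full_conversion", "one_sided", "one_sided_patch",
    "two_sided_trans", "two_sided_restoration", "two_chromatid",
)
CO_CLASSES = (
    "none", "no_strand_transfer", "full_conversion",
    "one_sided_unidirectional", "one_sided_bidirectional",
    "two_sided_unidirectional", "two_sided_bidirectional", "symmetric_hDNA",
)


@dataclass
class EventCategory:
    multi_dsb: str = "none"
    trans_dsb: bool | None = False    # None = not applicable (MMR-proficient tetrad)
    nco_class: str = "none"
    co_class: str = "none"
    template_switch: set = field(default_factory=set)
    qc_flags: set = field(default_factory=set)
    polarity_limited: bool = False


@dataclass
class HotspotTrack:
    """Sorted DSB-hotspot intervals per chromosome, half-open [start, end)."""

    intervals: dict     # chrom -> (starts array, ends array), sorted by start

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "HotspotTrack":
        out = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            starts = sub["start"].to_numpy(dtype=np.int64)
            ends = sub["end"].to_numpy(dtype=np.int64)
            if np.any(ends <= starts):
                raise ValueError("hotspot intervals must satisfy start < end")
            out[chrom] = (starts, ends)
        return cls(intervals=out)

    def overlaps(self, chrom: str, lo: float, hi: float) -> bool:
        """Any interval intersecting the closed span [lo, hi]?"""
        if chrom not in self.intervals:
            return False
        starts, ends = self.intervals[chrom]
        i = int(np.searchsorted(ends, lo, "right"))   # first interval with end > lo
        return i < starts.size and starts[i] <= hi


# ---------------------------------------------------------------------------
# helpers


def _is_double(seg: Segment) -> bool:
    return seg.pattern.n_a in (8, 0) or seg.pattern.n_a in (7, 1)


def _chromatid_states(ev: RecombinationEvent, k: int) -> np.ndarray:
    """Per-event-column state of chromatid k: -2 het, else the shared value."""
    cols = slice(ev.start_idx, ev.end_idx + 1)
    m = ev.geno[2 * k, cols].astype(np.int16)
    d = ev.geno[2 * k + 1, cols].astype(np.int16)
    out = np.where(m == d, m, -2)
    return out


def _column_donor(ev: RecombinationEvent, col: int) -> int | None:
    """Conversion direction of one column from its segregation ratio."""
    n_a = int(np.sum(ev.geno[:, col] == PARENT_A))
    if n_a > 4:
        return PARENT_A
    if n_a < 4:
        return 1 - PARENT_A
    return None


def _sisters(ev: RecombinationEvent, k1: int, k2: int) -> bool:
    """Sisterhood = identical parental identity on the flanks."""
    return ev.chromatid_flank_identity(k1) == ev.chromatid_flank_identity(k2)


# ---------------------------------------------------------------------------
# multi-DSB classes


def classify_multi_dsb(ev: RecombinationEvent) -> str:
    """Conservative multi-DSB class of an event (see module docstring)."""
    if ev.type_u:
        return "none"
    if ev.co_count == 2 and len(ev.changed_chromatids) == 4:
        return "dCO"
    if ev.co_count == 1 and ev.nco_runs:
        return "CO_plus_NCO"
    if ev.co_count == 0 and len(ev.nco_runs) == 2:
        k1, k2 = sorted(ev.nco_runs)
        if _sisters(ev, k1, k2):
            return "dNCO_sister"
        span1 = (ev.nco_runs[k1][0][0], ev.nco_runs[k1][-1][1])
        span2 = (ev.nco_runs[k2][0][0], ev.nco_runs[k2][-1][1])
        if span1 == span2:
            return "dNCO_overlap"
    return "none"


def detect_trans_dsb(ev: RecombinationEvent, mode: str = "octad") -> tuple[bool | None, set]:
    """8:0/7:1 trans-DSB evidence; returns (flag, qc flags).

    In MMR-proficient tetrads heteroduplex strands are invisible, 7:1
    segments cannot arise, and the assay is reported not-applicable
    (None) rather than negative.  Isolated 8:0 segments with no adjacent
    heteroduplex segment do not count and raise a QC flag instead.
    """
    if mode == "tetrad":
        return None, set()
    qc: set = set()
    flag = False
    segs = ev.segments
    for i, s in enumerate(segs):
        na = s.pattern.n_a
        if na in (7, 1):
            flag = True
        elif na in (8, 0):
            left_h = i > 0 and segs[i - 1].pattern.n_discordant > 0
            right_h = i + 1 < len(segs) and segs[i + 1].pattern.n_discordant > 0
            if left_h or right_h:
                flag = True
            else:
                qc.add("no_flanking_hDNA_8_0")
    return flag, qc


# ---------------------------------------------------------------------------
# NCO / CO subcategories


def classify_nco(ev: RecombinationEvent) -> str:
    """Subclass of a pure noncrossover event (0 COs, >= 1 conversion tract)."""
    if ev.type_u or ev.co_count != 0 or not ev.nco_runs:
        return "none"
    if len(ev.nco_runs) >= 2:
        ks = sorted(ev.nco_runs)
        if len(ks) == 2 and not _sisters(ev, ks[0], ks[1]):
            return "two_chromatid"
        return "none"   # sister / >2-chromatid combinations are multi-DSB or complex
    (k, runs), = ev.nco_runs.items()
    if len(runs) >= 2:
        return "two_sided_restoration"
    s, e = runs[0]
    base = ev.chromatid_flank_identity(k)
    m = ev.geno[2 * k, s:e + 1]
    d = ev.geno[2 * k + 1, s:e + 1]
    het = m != d
    if not het.any():
        return "full_conversion"
    # strand polarity of each heteroduplex column: which member of the
    # mother/daughter pair received the homologue's allele
    mother_conv = het & (d == base)
    daughter_conv = het & (m == base)
    if mother_conv.any() and daughter_conv.any():
        # trans hDNA: adjacent half-conversion tracts of opposite polarity
        return "two_sided_trans"
    if (~het & (m != base)).any():
        return "one_sided_patch"
    return "one_sided"


def _co_joint_transfer(ev: RecombinationEvent) -> dict:
    """Transfer tracts of the two recombining chromatids.

    Fits one joint switch point for the pair (columns before it are
    expected in the pre-CO configuration, columns after in the post-CO
    configuration; heteroduplex columns are neutral) and marks as
    transfer every heteroduplex column plus every homozygous column
    violating the fitted expectation (full-conversion tracts).  Reports,
    per chromatid, the maximal transfer runs and whether the
    mother/daughter orientation of its heteroduplex columns flips (the
    trans-hDNA signature).
    """
    c1, c2 = ev.changed_chromatids[:2]
    n = ev.n_markers
    out = {"runs": {c1: [], c2: []}, "flip": {c1: False, c2: False},
           "any_het": False, "donors": set()}
    if n == 0:
        return out
    cols = slice(ev.start_idx, ev.end_idx + 1)
    mm_pre = np.zeros(n, dtype=np.int16)
    mm_post = np.zeros(n, dtype=np.int16)
    per_k = {}
    for k in (c1, c2):
        m = ev.geno[2 * k, cols].astype(np.int16)
        d = ev.geno[2 * k + 1, cols].astype(np.int16)
        het = m != d
        per_k[k] = (m, d, het)
        left = ev.left_vec[2 * k]
        right = ev.right_vec[2 * k]
        mm_pre += (~het) & (m != left)
        mm_post += (~het) & (m != right)
    cost = np.concatenate([[0], np.cumsum(mm_pre)]) + \
        np.concatenate([np.cumsum(mm_post[::-1])[::-1], [0]])
    s_star = int(np.argmin(cost))
    expect_pre = np.arange(n) < s_star
    for k in (c1, c2):
        m, d, het = per_k[k]
        left = ev.left_vec[2 * k]
        right = ev.right_vec[2 * k]
        expected = np.where(expect_pre, left, right)
        mismatch = (~het) & (m != expected)
        transfer = het | mismatch
        out["runs"][k] = [
            (a + ev.start_idx, b + ev.start_idx) for a, b in _runs(transfer)
        ]
        if het.any():
            out["any_het"] = True
            orient = m[het] == PARENT_A
            out["flip"][k] = bool(orient.any() and (~orient).any())
        for i in np.flatnonzero(transfer):
            if het[i]:
                dn = _column_donor(ev, i + ev.start_idx)
            else:
                dn = int(m[i])   # conversion tract donates its own identity
            if dn is not None:
                out["donors"].add(dn)
    return out


def classify_co(ev: RecombinationEvent) -> str:
    """Subclass of a single-crossover event from its transfer-tract layout.

    One- vs two-sidedness reflects strand transfer on one or both sides
    of the initiating break: tracts on both recombining chromatids,
    trans hDNA (an orientation flip) on one chromatid, or restoration-
    separated tracts all read as two-sided.  Direction comes from the
    column ratios: converted markers deriving from both parents make the
    event bidirectional.
    """
    if ev.type_u or ev.co_count != 1:
        return "none"
    if any(s.pattern.n_a == 4 and s.pattern.n_discordant > 0 for s in ev.segments):
        return "symmetric_hDNA"
    if all(s.pattern.is_mendelian for s in ev.segments):
        return "no_strand_transfer"
    jt = _co_joint_transfer(ev)
    runs = jt["runs"]
    total = sum(len(r) for r in runs.values())
    if total == 0:
        return "no_strand_transfer"
    if not jt["any_het"] and total == 1:
        return "full_conversion"
    chromatids_with_runs = sum(1 for r in runs.values() if r)
    two_sided = (
        chromatids_with_runs == 2
        or any(jt["flip"].values())
        or any(len(r) >= 2 for r in runs.values())
    )
    sided = "two_sided" if two_sided else "one_sided"
    direction = "unidirectional" if len(jt["donors"]) <= 1 else "bidirectional"
    return f"{sided}_{direction}"


# ---------------------------------------------------------------------------
# orchestration


def classify_event(
    ev: RecombinationEvent,
    mode: str = "octad",
    hotspots: HotspotTrack | None = None,
    polarity_known: np.ndarray | None = None,
) -> EventCategory:
    """Fill the full category record of one event (stored on ``ev.category``)."""
    cat = EventCategory()
    if polarity_known is not None:
        involved = set(ev.changed_chromatids) | set(ev.nco_runs)
        cat.polarity_limited = any(not polarity_known[k] for k in involved)
    if ev.type_u:
        ev.category = cat
        return cat
    cat.multi_dsb = classify_multi_dsb(ev)
    cat.trans_dsb, qc = detect_trans_dsb(ev, mode)
    cat.qc_flags |= qc
    # final NCO tally: double NCOs count two initiations
    if cat.multi_dsb in ("dNCO_sister", "dNCO_overlap"):
        ev.nco_count = 2
    elif cat.multi_dsb == "CO_plus_NCO":
        ev.nco_count = min(2, len(ev.nco_runs))
    elif ev.co_count == 0 and ev.nco_runs:
        ev.nco_count = 1 if len(ev.nco_runs) <= 2 else 2
    else:
        ev.nco_count = 0
    if cat.multi_dsb == "none":
        if ev.co_count == 0 and ev.nco_runs:
            cat.nco_class = classify_nco(ev)
        elif ev.co_count == 1:
            cat.co_class = classify_co(ev)
    # template-switch signatures
    if cat.nco_class == "two_sided_restoration":
        cat.template_switch.add("two_sided_NCO_central_restoration")
    if cat.co_class == "symmetric_hDNA":
        cat.template_switch.add("CO_symmetric_hDNA")
    if cat.nco_class in ("one_sided", "one_sided_patch") and hotspots is not None:
        if not hotspot_overlap(ev, hotspots):
            cat.template_switch.add("one_sided_NCO_off_hotspot")
    ev.category = cat
    return cat


def classify_all(
    events: list[RecombinationEvent],
    mode: str = "octad",
    hotspots: HotspotTrack | None = None,
    polarity_known: np.ndarray | None = None,
) -> list[EventCategory]:
    return [classify_event(ev, mode, hotspots, polarity_known) for ev in events]


def hotspot_overlap(ev: RecombinationEvent, track: HotspotTrack) -> bool:
    """Does any hotspot intersect the maximal possible extent of the event?

    The maximal extent runs from the nearest flanking Mendelian marker on
    the left to the nearest on the right (the converted tract could reach
    up to, but not past, those markers).
    """
    if not track.intervals:
        return False
    lo = ev.left_flank_pos if ev.left_flank_pos is not None else ev.start_pos
    hi = ev.right_flank_pos if ev.right_flank_pos is not None else ev.end_pos
    return track.overlaps(ev.chrom, lo, hi)


# ---------------------------------------------------------------------------
# quality control across meioses


@dataclass
class QCReport:
    dropped: pd.DataFrame
    flagged_meioses: set

    def summary(self) -> str:
        return (
            f"{len(self.dropped)} events dropped, "
            f"{len(self.flagged_meioses)} meioses flagged premeiotic_suspect"
        )


def _isolated_80_only(ev: RecombinationEvent) -> bool:
    """True when the event's only anomaly is 8:0 with no adjacent hDNA."""
    if ev.co_count:
        return False
    doubles = [s for s in ev.segments if s.pattern.n_a in (8, 0)]
    if not doubles or len(doubles) != len(ev.segments):
        return False
    return all(s.pattern.n_discordant == 0 for s in ev.segments)


def qc_filter(
    events_by_meiosis: dict,
    het_fractions: dict | None = None,
    block_bp: int = 100_000,
    disomy_fraction: float = 0.8,
) -> tuple[dict, QCReport]:
    """Mitotic-artefact filter over one or more meioses.

    Drops events whose only anomaly is 8:0 segregation without adjacent
    heteroduplex, and 8:0 segments recurring at the identical locus in
    more than one meiosis (presumed reference mis-annotation).  Flags a
    meiosis ``premeiotic_suspect`` when it contains a chromosome-scale
    (> ``block_bp``) 8:0 block, or — given ``het_fractions`` mapping
    (meiosis, chrom) to per-spore heteroduplex fractions — when a
    chromosome is heteroduplex across > ``disomy_fraction`` of markers in
    exactly two spores (disomy signature).  Flagged meioses should be
    excluded from count statistics but retain their event lengths.
    """
    # recurrent 8:0 loci across meioses
    locus_meioses: dict[tuple, set] = {}
    for mid, events in events_by_meiosis.items():
        for ev in events:
            for s in ev.segments:
                if s.pattern.n_a in (8, 0):
                    key = (ev.chrom, s.start_pos, s.end_pos)
                    locus_meioses.setdefault(key, set()).add(mid)
    recurrent = {k for k, v in locus_meioses.items() if len(v) > 1}

    dropped_rows = []
    flagged: set = set()
    filtered: dict = {}
    for mid, events in events_by_meiosis.items():
        kept = []
        for ev in events:
            reason = None
            if _isolated_80_only(ev):
                reason = "no_flanking_hDNA_8_0"
            elif any(
                (ev.chrom, s.start_pos, s.end_pos) in recurrent
                for s in ev.segments
                if s.pattern.n_a in (8, 0)
            ):
                reason = "recurrent_locus"
            if any(
                s.pattern.n_a in (8, 0) and s.extent_bp > block_bp
                for s in ev.segments
            ):
                flagged.add(mid)
            if reason is None:
                kept.append(ev)
            else:
                if ev.category is not None:
                    ev.category.qc_flags.add(reason)
                dropped_rows.append(
                    {
                        "meiosis": mid,
                        "chrom": ev.chrom,
                        "start": ev.start_pos,
                        "end": ev.end_pos,
                        "reason": reason,
                    }
                )
        filtered[mid] = kept
    if het_fractions:
        for (mid, chrom), fracs in het_fractions.items():
            fracs = np.asarray(fracs, dtype=float)
            if int(np.sum(fracs > disomy_fraction)) == 2:
                flagged.add(mid)
    report = QCReport(
        dropped=pd.DataFrame(
            dropped_rows, columns=["meiosis", "chrom", "start", "end", "reason"]
        ),
        flagged_meioses=flagged,
    )
    return filtered, report
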