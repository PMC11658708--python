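"""Synthetic hybrid meioses with known ground truth.

Generates the three inputs the analysis consumes — a hybrid marker map,
per-chromosome strand matrices, and pileup-style per-site allele counts —
with the statistical structure of an S288c x SK1 octad experiment:

* ~65,000 markers with exponential inter-marker spacing (mean ~169 bp);
* crossovers placed by a gamma renewal process along each chromosome
  (shape 1 = no interference, larger shapes = more even spacing), with
  length-proportional allocation across the 16 chromosomes;
* noncrossovers as one-sided heteroduplex tracts on a single chromatid;
* multi-DSB clusters (dCO, dNCO on sisters, perfectly overlapping dNCO on
  homologues, CO+NCO on a third chromatid) with intra-cluster spacing
  below the 1.5 kb event-merging distance;
* Msh2-dependent mismatch repair: heteroduplex tracts are retained in the
  deficient background and resolved to full conversion or restoration in
  the proficient background;
* Poisson read depth and a symmetric per-read error rate.

Every planted event is recorded in a :class:`SimTruth` so that downstream
recovery can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import GenomeModel
from .matrix import PARENT_A, PARENT_B, StrandMatrix

__all__ = [
    "SimParams",
    "PlantedTract",
    "PlantedEvent",
    "SimTruth",
    "generate_marker_map",
    "simulate_meiosis",
    "emit_site_counts",
]

_BASES = np.array(list("ACGT"))

MULTI_DSB_KINDS = ("dCO", "dNCO_sister", "dNCO_overlap", "CO_plus_NCO")


@dataclass(frozen=True)
class SimParams:
    """Per-meiosis generative parameters.

    ``mean_co`` is the expected genome-wide crossover count; ``gamma_shape``
    is the interference shape of the inter-CO renewal process (1 =
    exponential/random).  ``nco_co_ratio`` scales the independent NCO count.
    Tract lengths are normal draws (bp) clipped at 1.  ``mmr`` is
    "deficient" (heteroduplex retained, the msh2-delta situation) or
    "proficient" (each tract converts with probability ``p_conversion``
    else restores).  ``multi_dsb_rate`` is the expected number of planted
    two-DSB clusters per meiosis, with intra-cluster spacing drawn
    uniformly between the two spacing bounds (kept < 1500 bp so the two
    initiations fall in a single called event).
    """

    mean_co: float = 90.0
    gamma_shape: float = 2.0
    nco_co_ratio: float = 1.0 / 3.0
    hdna_len_mean: float = 1500.0
    hdna_len_sd: float = 300.0
    conv_len_mean: float = 1500.0
    conv_len_sd: float = 300.0
    mmr: str = "deficient"
    p_conversion: float = 0.5
    mmr_resolution: str = "tract"   # or "marker"
    multi_dsb_rate: float = 5.0
    cluster_spacing_min: float = 50.0
    cluster_spacing_max: float = 1400.0
    min_event_sep: float = 0.0   # bp; reject inter-CO gaps below this (recovery runs)
    depth_mean: float = 45.0
    error_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_co < 0 or self.nco_co_ratio < 0 or self.multi_dsb_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be > 0")
        if not 0.0 <= self.p_conversion <= 1.0:
            raise ValueError("p_conversion must lie in [0, 1]")
        if self.mmr not in ("deficient", "proficient"):
            raise ValueError("mmr must be 'deficient' or 'proficient'")
        if self.mmr_resolution not in ("tract", "marker"):
            raise ValueError("mmr_resolution must be 'tract' or 'marker'")
        if not (0 < self.cluster_spacing_min <= self.cluster_spacing_max < 1500):
            raise ValueError("cluster spacing must satisfy 0 < min <= max < 1500")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must lie in [0, 0.5)")


@dataclass(frozen=True)
class PlantedTract:
    strand: int           # 0..7
    start: int            # bp, inclusive
    end: int              # bp, exclusive
    outcome: str          # "retained-hDNA" | "converted" | "restored"


@dataclass(frozen=True)
class PlantedEvent:
    chrom: str
    kind: str                      # CO | NCO | dCO | dNCO_sister | dNCO_overlap | CO_plus_NCO
    dsb_positions: tuple[int, ...]
    chromatids: tuple[int, ...]    # ids 0-3
    tracts: tuple[PlantedTract, ...]

    @property
    def co_count(self) -> int:
        return {"CO": 1, "dCO": 2, "CO_plus_NCO": 1}.get(self.kind, 0)

    @property
    def nco_count(self) -> int:
        return {"NCO": 1, "CO_plus_NCO": 1, "dNCO_sister": 2, "dNCO_overlap": 2}.get(
            self.kind, 0
        )

    @property
    def span(self) -> tuple[int, int]:
        lo = min(self.dsb_positions)
        hi = max(self.dsb_positions)
        for t in self.tracts:
            lo = min(lo, t.start)
            hi = max(hi, t.end)
        return lo, hi


@dataclass
class SimTruth:
    """Ground truth for one simulated meiosis."""

    events: list[PlantedEvent] = field(default_factory=list)

    def co_counts_per_chrom(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for ev in self.events:
            out[ev.chrom] = out.get(ev.chrom, 0) + ev.co_count
        return {c: n for c, n in out.items()}

    def simple_events(self) -> list[PlantedEvent]:
        return [ev for ev in self.events if ev.kind in ("CO", "NCO")]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ev in self.events:
            lo, hi = ev.span
            rows.append(
                {
                    "chrom": ev.chrom,
                    "kind": ev.kind,
                    "dsb_positions": ",".join(map(str, ev.dsb_positions)),
                    "chromatids": ",".join(map(str, ev.chromatids)),
                    "start": lo,
                    "end": hi,
                    "n_tracts": len(ev.tracts),
                }
            )
        return pd.DataFrame(
            rows,
            columns=["chrom", "kind", "dsb_positions", "chromatids", "start", "end", "n_tracts"],
        )


# ---------------------------------------------------------------------------
# marker map


def generate_marker_map(
    genome: GenomeModel,
    mean_spacing: float = 169.0,
    indel_fraction: float = 0.058,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw a hybrid marker map with exponential inter-marker spacing.

    Returns a frame with columns chrom, pos (1-based), allele_a, allele_b,
    kind (SNP | insertion | deletion).  A chromosome much shorter than the
    mean spacing may legitimately receive zero markers.
    """
    if mean_spacing <= 0:
        raise ValueError("mean_spacing must be > 0")
    if not 0.0 <= indel_fraction <= 1.0:
        raise ValueError("indel_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    frames = []
    for name, length in zip(genome.names, genome.lengths):
        # oversample gaps, keep the prefix within the chromosome
        n_guess = max(16, int(2 * length / mean_spacing + 8 * np.sqrt(length / mean_spacing)))
        gaps = rng.exponential(mean_spacing, size=n_guess)
        pos = np.cumsum(gaps)
        while pos.size and pos[-1] <= length:
            extra = rng.exponential(mean_spacing, size=n_guess)
            pos = np.concatenate([pos, pos[-1] + np.cumsum(extra)])
        pos = pos[pos <= length]
        pos = np.unique(np.maximum(1, np.floor(pos).astype(np.int64)))
        n = pos.size
        if n == 0:
            continue
        is_indel = rng.random(n) < indel_fraction
        kind = np.where(is_indel, np.where(rng.random(n) < 0.5, "insertion", "deletion"), "SNP")
        base_idx = rng.integers(0, 4, size=n)
        base = _BASES[base_idx]
        alt = _BASES[(base_idx + rng.integers(1, 4, size=n)) % 4]
        allele_a = base.astype(object)
        allele_b = alt.astype(object)
        for i in np.flatnonzero(is_indel):
            if kind[i] == "insertion":
                allele_a[i] = base[i]
                allele_b[i] = base[i] + alt[i]
            else:
                allele_a[i] = base[i] + alt[i]
                allele_b[i] = base[i]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": name,
                    "pos": pos,
                    "allele_a": allele_a,
                    "allele_b": allele_b,
                    "kind": kind,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "allele_a", "allele_b", "kind"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# meiosis simulation


def _tract_cols(pos: np.ndarray, start: float, end: float) -> slice:
    return slice(int(np.searchsorted(pos, start, "left")),
                 int(np.searchsorted(pos, end, "left")))


def _draw_len(rng: np.random.Generator, mean: float, sd: float) -> float:
    return max(1.0, rng.normal(mean, sd))


def _resolve_tract(
    geno: np.ndarray,
    daughter_row: int,
    cols: slice,
    params: SimParams,
    rng: np.random.Generator,
) -> str:
    """Apply MMR to a freshly deposited hDNA tract; return the outcome label."""
    if params.mmr == "deficient":
        return "retained-hDNA"
    mother_row = daughter_row - 1
    if params.mmr_resolution == "tract":
        if rng.random() < params.p_conversion:
            geno[mother_row, cols] = geno[daughter_row, cols]
            return "converted"
        geno[daughter_row, cols] = geno[mother_row, cols]
        return "restored"
    # per-marker resolution
    n = geno[daughter_row, cols].size
    convert = rng.random(n) < params.p_conversion
    m = geno[mother_row, cols].copy()
    d = geno[daughter_row, cols].copy()
    geno[mother_row, cols] = np.where(convert, d, m)
    geno[daughter_row, cols] = np.where(convert, d, m)
    return "converted" if convert.all() else ("restored" if not convert.any() else "mixed")


def _apply_co(
    geno: np.ndarray,
    pos: np.ndarray,
    x: int,
    recipient: int,
    partner: int,
    params: SimParams,
    rng: np.random.Generator,
) -> list[PlantedTract]:
    """Reciprocal arm exchange at ``x`` with canonical trans hDNA tracts.

    The DSB is on ``recipient``; both heteroduplex tracts carry the
    partner's (donor) alleles, one upstream of the exchange on the
    recipient and one downstream on the partner.
    """
    j = int(np.searchsorted(pos, x, "left"))
    donor_allele = int(geno[2 * partner, j])
    rows_r = [2 * recipient, 2 * recipient + 1]
    rows_q = [2 * partner, 2 * partner + 1]
    # reciprocal exchange of distal arms
    tmp = geno[rows_r, j:].copy()
    geno[rows_r, j:] = geno[rows_q, j:]
    geno[rows_q, j:] = tmp
    tracts = []
    la = _draw_len(rng, params.hdna_len_mean, params.hdna_len_sd)
    lb = _draw_len(rng, params.hdna_len_mean, params.hdna_len_sd)
    cols_l = _tract_cols(pos, x - la, x)
    cols_r = _tract_cols(pos, x, x + lb)
    geno[2 * recipient + 1, cols_l] = donor_allele
    out_l = _resolve_tract(geno, 2 * recipient + 1, cols_l, params, rng)
    geno[2 * partner + 1, cols_r] = donor_allele
    out_r = _resolve_tract(geno, 2 * partner + 1, cols_r, params, rng)
    tracts.append(PlantedTract(2 * recipient + 1, int(x - la), int(x), out_l))
    tracts.append(PlantedTract(2 * partner + 1, int(x), int(x + lb), out_r))
    return tracts


def _apply_nco(
    geno: np.ndarray,
    pos: np.ndarray,
    x: int,
    recipient: int,
    params: SimParams,
    rng: np.random.Generator,
    length: float | None = None,
    full: bool = False,
) -> list[PlantedTract]:
    """One-sided conversion tract on a single chromatid starting at ``x``."""
    j = int(np.searchsorted(pos, x, "left"))
    donor_allele = 1 - int(geno[2 * recipient, j])
    if length is None:
        length = _draw_len(
            rng,
            params.conv_len_mean if full else params.hdna_len_mean,
            params.conv_len_sd if full else params.hdna_len_sd,
        )
    if rng.random() < 0.5:
        cols = _tract_cols(pos, x - length, x)
        start, end = int(x - length), int(x)
    else:
        cols = _tract_cols(pos, x, x + length)
        start, end = int(x), int(x + length)
    if full:
        geno[2 * recipient, cols] = donor_allele
        geno[2 * recipient + 1, cols] = donor_allele
        return [PlantedTract(2 * recipient, start, end, "converted")]
    geno[2 * recipient + 1, cols] = donor_allele
    out = _resolve_tract(geno, 2 * recipient + 1, cols, params, rng)
    return [PlantedTract(2 * recipient + 1, start, end, out)]


def _chromatid_sides(geno: np.ndarray, j: int) -> tuple[list[int], list[int]]:
    side_a = [k for k in range(4) if geno[2 * k, j] == PARENT_A]
    side_b = [k for k in range(4) if geno[2 * k, j] == PARENT_B]
    return side_a, side_b


def simulate_meiosis(
    marker_map: pd.DataFrame,
    genome: GenomeModel,
    params: SimParams,
    seed: int | None = None,
) -> tuple[dict[str, StrandMatrix], SimTruth]:
    """Simulate one meiosis; return per-chromosome strand matrices and truth.

    Crossover positions come from a gamma renewal process with shape
    ``params.gamma_shape`` and a scale chosen so the genome-wide expected
    CO count is ``params.mean_co``; the mean inter-CO distance is then the
    same on every chromosome, which reproduces length-proportional
    allocation.  Events are planted only within the marker-covered span of
    each chromosome (an initiation in the terminal marker desert would be
    undetectable in principle).
    """
    if marker_map.empty:
        raise ValueError("marker map is empty")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    truth = SimTruth()
    matrices: dict[str, StrandMatrix] = {}
    mean_icd = genome.total_length / max(params.mean_co, 1e-9)
    scale = mean_icd / params.gamma_shape

    # keep planted initiations clear of the chromosome ends so their tracts
    # cannot swallow the terminal markers (which would make them type-U /
    # undetectable by construction rather than by chance)
    margin = max(
        params.hdna_len_mean + 4 * params.hdna_len_sd,
        params.conv_len_mean + 4 * params.conv_len_sd,
    )

    by_chrom = {c: g for c, g in marker_map.groupby("chrom", sort=False)}
    spans: dict[str, tuple[int, int]] = {}
    for name in genome.names:
        sub = by_chrom.get(name)
        if sub is None or len(sub) == 0:
            matrices[name] = StrandMatrix(
                chrom=name,
                positions=np.empty(0, dtype=np.int64),
                geno=np.empty((8, 0), dtype=np.int8),
            )
            continue
        pos = sub["pos"].to_numpy(dtype=np.int64)
        geno = np.empty((8, pos.size), dtype=np.int8)
        geno[0:4] = PARENT_A
        geno[4:8] = PARENT_B
        matrices[name] = StrandMatrix(chrom=name, positions=pos, geno=geno)
        spans[name] = (int(pos[0]), int(pos[-1]))

    # --- crossovers: gamma renewal per chromosome over the marker span
    if params.mean_co > 0:
        for name in genome.names:
            if name not in spans:
                continue
            lo, hi = spans[name]
            lo, hi = lo + margin, hi - margin
            if hi <= lo:
                continue
            sm = matrices[name]
            t = float(lo)
            while True:
                gap = rng.gamma(params.gamma_shape, scale)
                while gap < params.min_event_sep:
                    gap = rng.gamma(params.gamma_shape, scale)
                t += gap
                if t >= hi:
                    break
                x = int(t)
                j = int(np.searchsorted(sm.positions, x, "left"))
                r = int(rng.integers(0, 4))
                side_a, side_b = _chromatid_sides(sm.geno, j)
                others = side_b if r in side_a else side_a
                if not others:   # degenerate column inside another event
                    continue
                q = int(rng.choice(others))
                tracts = _apply_co(sm.geno, sm.positions, x, r, q, params, rng)
                truth.events.append(
                    PlantedEvent(name, "CO", (x,), (r, q), tuple(tracts))
                )

    # --- independent noncrossovers, length-proportionally allocated
    n_nco = rng.poisson(params.mean_co * params.nco_co_ratio)
    p = genome.probabilities
    for _ in range(n_nco):
        name = genome.names[int(rng.choice(len(p), p=p))]
        if name not in spans:
            continue
        lo, hi = spans[name]
        lo, hi = int(lo + margin), int(hi - margin)
        if hi <= lo:
            continue
        sm = matrices[name]
        x = int(rng.integers(lo, hi))
        r = int(rng.integers(0, 4))
        tracts = _apply_nco(sm.geno, sm.positions, x, r, params, rng)
        truth.events.append(PlantedEvent(name, "NCO", (x,), (r,), tuple(tracts)))

    # --- clustered multi-DSB events
    n_multi = rng.poisson(params.multi_dsb_rate)
    for _ in range(n_multi):
        name = genome.names[int(rng.choice(len(p), p=p))]
        if name not in spans:
            continue
        lo, hi = spans[name]
        lo, hi = int(lo + margin), int(hi - margin - 2000)
        if hi <= lo:
            continue
        sm = matrices[name]
        x = int(rng.integers(lo, hi))
        d = int(rng.uniform(params.cluster_spacing_min, params.cluster_spacing_max))
        kind = MULTI_DSB_KINDS[int(rng.integers(0, len(MULTI_DSB_KINDS)))]
        j = int(np.searchsorted(sm.positions, x, "left"))
        side_a, side_b = _chromatid_sides(sm.geno, j)
        if len(side_a) != 2 or len(side_b) != 2:
            continue   # landed inside an existing conversion; skip cluster
        tracts: list[PlantedTract] = []
        if kind == "dCO":
            r1 = int(rng.choice(side_a))
            q1 = int(rng.choice(side_b))
            tracts += _apply_co(sm.geno, sm.positions, x, r1, q1, params, rng)
            r2 = [k for k in side_a if k != r1][0]
            q2 = [k for k in side_b if k != q1][0]
            tracts += _apply_co(sm.geno, sm.positions, x + d, r2, q2, params, rng)
            chromatids = (r1, q1, r2, q2)
        elif kind == "dNCO_sister":
            side = side_a if rng.random() < 0.5 else side_b
            l1 = min(_draw_len(rng, params.hdna_len_mean, params.hdna_len_sd), 1400.0)
            l2 = min(_draw_len(rng, params.hdna_len_mean, params.hdna_len_sd), 1400.0)
            tracts += _apply_nco(sm.geno, sm.positions, x, side[0], params, rng, length=l1)
            tracts += _apply_nco(sm.geno, sm.positions, x + d, side[1], params, rng, length=l2)
            chromatids = (side[0], side[1])
        elif kind == "dNCO_overlap":
            r1 = int(rng.choice(side_a))
            r2 = int(rng.choice(side_b))
            length = min(_draw_len(rng, params.conv_len_mean, params.conv_len_sd), 1400.0)
            pos = sm.positions
            j0 = int(np.searchsorted(pos, x, "left"))
            j1 = int(np.searchsorted(pos, x + length, "left")) - 1
            if j0 == 0 or j1 < j0:
                continue
            # the perfectly overlapping tract reads as a rearranged 4:4 run
            # bounded by two switch points; shrink it until those stay within
            # one called event (midpoint separation < the 1.5 kb merge gap)
            left_mid = 0.5 * (pos[j0 - 1] + pos[j0])
            while j1 > j0 and j1 + 1 < pos.size and \
                    0.5 * (pos[j1] + pos[j1 + 1]) - left_mid >= 1400.0:
                j1 -= 1
            if j1 + 1 >= pos.size or 0.5 * (pos[j1] + pos[j1 + 1]) - left_mid >= 1400.0:
                continue
            cols = slice(j0, j1 + 1)
            sm.geno[2 * r1: 2 * r1 + 2, cols] = PARENT_B
            sm.geno[2 * r2: 2 * r2 + 2, cols] = PARENT_A
            end = int(pos[j1]) + 1
            tracts.append(PlantedTract(2 * r1, x, end, "converted"))
            tracts.append(PlantedTract(2 * r2, x, end, "converted"))
            chromatids = (r1, r2)
        else:  # CO_plus_NCO
            r1 = int(rng.choice(side_a))
            q1 = int(rng.choice(side_b))
            tracts += _apply_co(sm.geno, sm.positions, x, r1, q1, params, rng)
            third = [k for k in range(4) if k not in (r1, q1)]
            c = int(rng.choice(third))
            l3 = min(_draw_len(rng, params.hdna_len_mean, params.hdna_len_sd), 1400.0)
            tracts += _apply_nco(sm.geno, sm.positions, x + d, c, params, rng, length=l3)
            chromatids = (r1, q1, c)
        truth.events.append(
            PlantedEvent(name, kind, (x, x + d), chromatids, tuple(tracts))
        )

    return matrices, truth


def score_recovery(truth: SimTruth, events) -> dict:
    """Score called events against planted ground truth.

    A planted simple CO is recovered when a called non-type-U event with
    co_count >= 1 overlaps its span; a planted simple NCO when a called
    event with nco_count >= 1 and co_count == 0 overlaps its tract and is
    not classified multi-DSB.  Per-chromosome CO counts compare the summed
    called CO count with the planted one (double COs count two).
    """
    by_chrom: dict[str, list] = {}
    for ev in events:
        by_chrom.setdefault(ev.chrom, []).append(ev)

    def _overlapping(chrom, lo, hi):
        return [
            ev for ev in by_chrom.get(chrom, [])
            if not ev.type_u and ev.start_pos <= hi and ev.end_pos >= lo
        ]

    n_simple = n_recovered = 0
    for pe in truth.simple_events():
        n_simple += 1
        lo, hi = pe.span
        hits = _overlapping(pe.chrom, lo, hi)
        if pe.kind == "CO":
            if any(ev.co_count >= 1 for ev in hits):
                n_recovered += 1
        else:
            if any(
                ev.co_count == 0 and ev.nco_count >= 1
                and (ev.category is None or ev.category.multi_dsb == "none")
                for ev in hits
            ):
                n_recovered += 1

    truth_co = truth.co_counts_per_chrom()
    called_co: dict[str, int] = {}
    for ev in events:
        if not ev.type_u:
            called_co[ev.chrom] = called_co.get(ev.chrom, 0) + ev.co_count
    chroms = set(truth_co) | set(called_co)
    exact = all(truth_co.get(c, 0) == called_co.get(c, 0) for c in chroms)
    return {
        "n_simple": n_simple,
        "n_recovered": n_recovered,
        "recovery_rate": n_recovered / n_simple if n_simple else float("nan"),
        "per_chrom_co_exact": exact,
        "truth_co": truth_co,
        "called_co": called_co,
    }


# ---------------------------------------------------------------------------
# pileup-style site counts


def _strand_counts(
    g: np.ndarray, depth: np.ndarray, error_rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Counts (n_ref, n_var, n_other) for reads drawn from single strands."""
    correct = rng.binomial(depth, 1.0 - error_rate)
    wrong = depth - correct
    to_opposite = rng.binomial(wrong, 0.5)
    n_other = wrong - to_opposite
    n_ref = np.where(g == PARENT_A, correct, to_opposite)
    n_var = np.where(g == PARENT_A, to_opposite, correct)
    return n_ref, n_var, n_other


def emit_site_counts(
    matrices: dict[str, StrandMatrix],
    depth_mean: float = 45.0,
    error_rate: float = 0.002,
    seed: int | None = None,
    mode: str = "octad",
    sample_prefix: str = "",
    colony_strands: dict[int, int] | None = None,
) -> pd.DataFrame:
    """Emit per-sample per-marker allele counts from strand matrices.

    mode="octad": one sample per strand (8 samples, ``s0``..``s7``).
    mode="tetrad": one sample per spore colony (4 samples, ``c0``..``c3``);
    each read derives from the spore's mother or daughter strand with equal
    probability, so retained-hDNA markers yield mixed counts.
    ``colony_strands`` optionally adds single-colony resequencing samples
    (``colony{k}``) drawing from one declared strand of spore ``k``.
    """
    if depth_mean <= 0:
        raise ValueError("depth_mean must be > 0")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must lie in [0, 0.5)")
    if mode not in ("octad", "tetrad"):
        raise ValueError("mode must be 'octad' or 'tetrad'")
    rng = np.random.default_rng(seed)
    frames = []
    for chrom in matrices:
        sm = matrices[chrom]
        n = sm.n_markers
        if n == 0:
            continue
        if mode == "octad":
            for row in range(8):
                depth = rng.poisson(depth_mean, size=n)
                n_ref, n_var, n_other = _strand_counts(
                    sm.geno[row], depth, error_rate, rng
                )
                frames.append(
                    pd.DataFrame(
                        {
                            "sample": f"{sample_prefix}s{row}",
                            "chrom": chrom,
                            "pos": sm.positions,
                            "n_ref": n_ref,
                            "n_var": n_var,
                            "n_other": n_other,
                            "depth": depth,
                        }
                    )
                )
        else:
            for spore in range(4):
                depth = rng.poisson(depth_mean, size=n)
                from_mother = rng.binomial(depth, 0.5)
                rm = _strand_counts(sm.geno[2 * spore], from_mother, error_rate, rng)
                rd = _strand_counts(
                    sm.geno[2 * spore + 1], depth - from_mother, error_rate, rng
                )
                frames.append(
                    pd.DataFrame(
                        {
                            "sample": f"{sample_prefix}c{spore}",
                            "chrom": chrom,
                            "pos": sm.positions,
                            "n_ref": rm[0] + rd[0],
                            "n_var": rm[1] + rd[1],
                            "n_other": rm[2] + rd[2],
                            "depth": depth,
                        }
                    )
                )
        if colony_strands:
            for spore, row in colony_strands.items():
                depth = rng.poisson(depth_mean, size=n)
                n_ref, n_var, n_other = _strand_counts(
                    sm.geno[row], depth, error_rate, rng
                )
                frames.append(
                    pd.DataFrame(
                        {
                            "sample": f"{sample_prefix}colony{spore}",
                            "chrom": chrom,
                            "pos": sm.positions,
                            "n_ref": n_ref,
                            "n_var": n_var,
                            "n_other": n_other,
                            "depth": depth,
                        }
                    )
                )
    if not frames:
        return pd.DataFrame(
            columns=["sample", "chrom", "pos", "n_ref", "n_var", "n_other", "depth"]
        )
    return pd.concat(frames, ignore_index=True)
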