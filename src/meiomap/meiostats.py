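"""Per-meiosis and per-genotype statistics.

Covers the spatial-regulation analyses downstream of event calling:
event mid-lengths and their quartiles, the length-proportional random
allocation null for non-exchange chromosomes (crossover assurance),
inter-crossover distance (ICD) gamma modelling (crossover interference:
shape 1 = exponential = random spacing; larger shapes = more even
spacing), matched exponential reference samples, the CO:NCO homeostasis
trend, telomere/centromere distance curves, and the hypothesis tests
used throughout (two-sided Fisher, Wilcoxon rank-sum with continuity
correction, Welch t, two-sample KS, Benjamini-Hochberg adjustment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .events import RecombinationEvent
from .genome import GenomeModel

logger = logging.getLogger(__name__)

__all__ = [
    "MeiosisSummary",
    "GammaFit",
    "NonExchangeSim",
    "event_midlength",
    "length_quartiles",
    "simulate_nonexchange",
    "nonexchange_pvalue",
    "aggregate_nonexchange",
    "co_positions_from_events",
    "compute_icds",
    "fit_gamma_mle",
    "random_icd_reference",
    "homeostasis_trend",
    "distance_to_feature_cdf",
    "stat_tests",
    "adjust_pvalues",
    "summarize_meiosis",
]


# ---------------------------------------------------------------------------
# tract lengths


def event_midlength(ev: RecombinationEvent) -> float:
    """Mid-length estimate of an event's true tract length (bp).

    Distance between the midpoints of the two inter-marker intervals
    flanking the event: midpoint(last event marker, first downstream
    Mendelian marker) minus midpoint(last upstream Mendelian marker,
    first event marker).  Undefined for type-U events (no flank); zero
    for a pure haplotype switch with no converted marker.
    """
    if ev.type_u:
        raise ValueError("mid-length is undefined for type-U events")
    if ev.n_markers == 0:
        return 0.0
    left = 0.5 * (ev.positions[ev.start_idx - 1] + ev.positions[ev.start_idx])
    right = 0.5 * (ev.positions[ev.end_idx] + ev.positions[ev.end_idx + 1])
    return float(right - left)


def length_quartiles(lengths) -> tuple[float, float, float]:
    """(lower quartile, median, upper quartile) of mid-lengths."""
    arr = np.asarray(list(lengths), dtype=float)
    if arr.size == 0:
        raise ValueError("no lengths supplied")
    q1, q2, q3 = np.percentile(arr, [25, 50, 75])
    return float(q1), float(q2), float(q3)


# ---------------------------------------------------------------------------
# non-exchange chromosome simulation


def simulate_nonexchange(
    genome: GenomeModel | np.ndarray,
    n_co: int,
    replicates: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Zero-CO chromosome counts under length-proportional random allocation.

    Each replicate drops ``n_co`` crossovers multinomially with
    probabilities p_i = L_i / sum(L) and records how many chromosomes
    received none.
    """
    if n_co < 1:
        raise ValueError("n_co must be >= 1")
    p = genome.probabilities if isinstance(genome, GenomeModel) else np.asarray(genome, float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("allocation probabilities must sum to 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    alloc = rng.multinomial(n_co, p, size=replicates)
    return (alloc == 0).sum(axis=1)


@dataclass
class NonExchangeSim:
    """Cached random-allocation null over a grid of total CO counts."""

    genome: GenomeModel | np.ndarray
    replicates: int = 10_000
    n_min: int = 1
    n_max: int = 200
    seed: int | None = None
    extend: bool = False     # allow N outside the grid (simulated on demand)
    _cache: dict = field(default_factory=dict, repr=False)

    def counts(self, n_co: int) -> np.ndarray:
        if not self.extend and not (self.n_min <= n_co <= self.n_max):
            raise ValueError(f"n_co={n_co} outside the simulation grid "
                             f"[{self.n_min}, {self.n_max}]")
        if n_co not in self._cache:
            # per-N child seed keeps the grid reproducible and order-free
            rng = np.random.default_rng(
                None if self.seed is None else (self.seed, n_co)
            )
            self._cache[n_co] = simulate_nonexchange(
                self.genome, n_co, self.replicates, rng=rng
            )
        return self._cache[n_co]

    def tail_probability(self, observed_k: int, n_co: int, tail: str) -> float:
        counts = self.counts(n_co)
        if tail == "greater":
            return float(np.mean(counts >= observed_k))
        if tail == "lesser":
            return float(np.mean(counts <= observed_k))
        raise ValueError("tail must be 'greater' or 'lesser'")


def nonexchange_pvalue(
    observed_k: int, n_co: int, sim: NonExchangeSim, tail: str = "greater"
) -> float:
    """Empirical chance of an equal-or-more-extreme non-exchange count."""
    return sim.tail_probability(observed_k, n_co, tail)


def aggregate_nonexchange(probabilities) -> float:
    """Genotype-level probability: median of per-meiosis probabilities
    raised to the power of the number of meioses.

    This reproduces the published aggregation verbatim; note it is not a
    standard combined p-value (it is a summary statistic designed to damp
    outlier meioses).
    """
    probs = np.asarray(list(probabilities), dtype=float)
    if probs.size == 0:
        raise ValueError("no probabilities supplied")
    logger.warning(
        "median^n aggregation is the published procedure but is not a "
        "calibrated combined p-value"
    )
    return float(np.median(probs) ** probs.size)


# ---------------------------------------------------------------------------
# inter-crossover distances and gamma modelling


def _chromatid_switch_pos(ev: RecombinationEvent, k: int) -> float:
    """Haplotype switch position of one crossover chromatid.

    Midpoint of the inter-marker interval at the best monotone
    left-identity -> right-identity split of the chromatid's columns
    inside the event.
    """
    if ev.n_markers == 0:
        return ev.midpoint
    left = ev.left_vec[2 * k]
    right = ev.right_vec[2 * k]
    cols = slice(ev.start_idx, ev.end_idx + 1)
    m = ev.geno[2 * k, cols].astype(np.int16)
    d = ev.geno[2 * k + 1, cols].astype(np.int16)
    states = np.where(m == d, m, -2)
    is_l = states == left
    is_r = (states == right) & ~is_l
    pre_r = np.concatenate([[0], np.cumsum(is_r)])
    suf_l = np.concatenate([np.cumsum(is_l[::-1])[::-1], [0]])
    s = int(np.argmin(pre_r + suf_l))
    n = states.size
    lo = (
        ev.positions[ev.start_idx + s - 1] if s >= 1
        else ev.positions[ev.start_idx - 1]
    )
    hi = (
        ev.positions[ev.start_idx + s] if s < n
        else ev.positions[ev.end_idx + 1]
    )
    return 0.5 * float(lo + hi)


def co_anchor_positions(ev: RecombinationEvent) -> list[float]:
    """Crossover anchor positions of one event.

    A single CO is anchored at the mean of its two chromatids' haplotype
    switch positions; a double CO (four-chromatid double reciprocal
    exchange) resolves its two exchange points separately, pairing the
    chromatids of the two parents by switch proximity, so closely spaced
    double COs contribute their internal inter-CO distance.  Irregular
    events fall back to the event midpoint.
    """
    if ev.type_u or ev.co_count == 0:
        return []
    ch = ev.changed_chromatids
    if ev.co_count == 1 and len(ch) == 2:
        return [0.5 * (_chromatid_switch_pos(ev, ch[0]) + _chromatid_switch_pos(ev, ch[1]))]
    if ev.co_count == 2 and len(ch) == 4:
        side_a = [k for k in ch if ev.chromatid_flank_identity(k) == 1]
        side_b = [k for k in ch if ev.chromatid_flank_identity(k) == 0]
        if len(side_a) == 2 and len(side_b) == 2:
            sw = {k: _chromatid_switch_pos(ev, k) for k in ch}
            a1, a2 = side_a
            b1, b2 = side_b
            # pair one chromatid per parent, matching switch positions
            if abs(sw[a1] - sw[b1]) + abs(sw[a2] - sw[b2]) <= \
               abs(sw[a1] - sw[b2]) + abs(sw[a2] - sw[b1]):
                pairs = [(a1, b1), (a2, b2)]
            else:
                pairs = [(a1, b2), (a2, b1)]
            return [0.5 * (sw[x] + sw[y]) for x, y in pairs]
    return [ev.midpoint] * ev.co_count


def co_positions_from_events(events) -> dict[str, list[float]]:
    """Per-chromosome crossover anchor positions of called events."""
    out: dict[str, list[float]] = {}
    for ev in events:
        anchors = co_anchor_positions(ev)
        if anchors:
            out.setdefault(ev.chrom, []).extend(anchors)
    return out


def compute_icds(co_positions: dict[str, list[float]]) -> np.ndarray:
    """Successive distances between adjacent crossovers within chromosomes.

    Chromosomes with fewer than two COs contribute nothing; coincident
    anchors (double COs sharing one event span) yield no usable distance
    and are skipped.
    """
    icds: list[float] = []
    for _, positions in co_positions.items():
        p = np.sort(np.asarray(positions, dtype=float))
        if p.size < 2:
            continue
        d = np.diff(p)
        icds.extend(d[d > 0])
    return np.asarray(icds, dtype=float)


@dataclass(frozen=True)
class GammaFit:
    shape: float
    scale: float
    n: int
    loglik: float
    capped: bool = False

    @property
    def mean(self) -> float:
        return self.shape * self.scale


_SHAPE_CAP = 1e6


def fit_gamma_mle(x, min_n: int = 10) -> GammaFit:
    """Maximum-likelihood gamma fit of inter-crossover distances.

    Shape is found by solving the profile-likelihood score equation
    ``log(a) - psi(a) = log(mean) - mean(log x)``; the scale follows from
    the MLE mean identity shape*scale = sample mean.  Shape 1 indicates
    exponential (random) spacing; larger shapes indicate the more even
    spacing produced by crossover interference.  Near-constant data push
    the shape to infinity; it is capped with a warning.
    """
    x = np.asarray(list(x), dtype=float)
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} distances, got {x.size}")
    if np.any(x <= 0):
        raise ValueError("distances must be positive")
    m = x.mean()
    s = np.log(m) - np.mean(np.log(x))
    capped = False
    if s <= 1.0 / (2 * _SHAPE_CAP):
        logger.warning("near-constant distances: gamma shape capped at %g", _SHAPE_CAP)
        shape = _SHAPE_CAP
        capped = True
    else:
        a0 = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
        f = lambda a: np.log(a) - special.digamma(a) - s
        lo, hi = a0 / 8, a0 * 8
        while f(lo) < 0:
            lo /= 8
        while f(hi) > 0:
            hi *= 8
        shape = float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-14))
    scale = m / shape
    loglik = float(
        np.sum((shape - 1.0) * np.log(x) - x / scale)
        - x.size * (shape * np.log(scale) + special.gammaln(shape))
    )
    return GammaFit(shape=shape, scale=float(scale), n=int(x.size), loglik=loglik,
                    capped=capped)


def random_icd_reference(
    mean: float,
    n_events,
    n_cells: int = 10_000,
    seed: int | None = None,
) -> np.ndarray:
    """Matched exponential (gamma shape 1) reference ICD sample.

    For each simulated cell, draws as many ICDs as the matched
    experimental cell (``n_events`` scalar, or a per-cell sequence cycled
    over ``n_cells``) from an exponential with the experimental mean.
    """
    if mean <= 0:
        raise ValueError("mean must be > 0")
    rng = np.random.default_rng(seed)
    if np.isscalar(n_events):
        counts = np.full(n_cells, int(n_events))
    else:
        base = np.asarray(list(n_events), dtype=int)
        counts = base[np.arange(n_cells) % base.size]
    total = int(counts.sum())
    return rng.exponential(mean, size=total)


# ---------------------------------------------------------------------------
# homeostasis and feature distances


def homeostasis_trend(
    total_events, co_counts, nco_counts
) -> tuple[float, float]:
    """Least-squares fit of the CO:NCO ratio against total event count.

    A negative slope is the signature of crossover homeostasis (CO numbers
    maintained while total event numbers vary).  Meioses with zero NCOs
    are excluded with a warning.
    """
    tot = np.asarray(list(total_events), dtype=float)
    co = np.asarray(list(co_counts), dtype=float)
    nco = np.asarray(list(nco_counts), dtype=float)
    ok = nco > 0
    if not ok.all():
        logger.warning("%d meioses with zero NCOs excluded from the trend",
                       int((~ok).sum()))
    tot, co, nco = tot[ok], co[ok], nco[ok]
    if tot.size < 2:
        raise ValueError("need at least 2 usable meioses (3 recommended)")
    slope, intercept = np.polyfit(tot, co / nco, 1)
    return float(slope), float(intercept)


def distance_to_feature_cdf(
    midpoints: dict[str, np.ndarray] | list[tuple[str, float]],
    genome: GenomeModel,
    feature: str = "telomere",
) -> pd.DataFrame:
    """Empirical CDF of event-midpoint distances to the nearest telomere
    or to the centromere.

    Telomere distance of a midpoint ``x`` on a chromosome of length L is
    ``min(x - 1, L - x)`` (1-based ends).  Returns a frame with columns
    ``distance`` (sorted) and ``cum_fraction``.
    """
    if feature not in ("telomere", "centromere"):
        raise ValueError("feature must be 'telomere' or 'centromere'")
    pairs: list[tuple[str, float]] = []
    if isinstance(midpoints, dict):
        for chrom, arr in midpoints.items():
            pairs.extend((chrom, float(x)) for x in np.atleast_1d(arr))
    else:
        pairs = [(c, float(x)) for c, x in midpoints]
    dists = []
    for chrom, x in pairs:
        L = genome.length_of(chrom)
        if feature == "telomere":
            dists.append(min(x - 1, L - x))
        else:
            dists.append(abs(x - genome.centromere_of(chrom)))
    d = np.sort(np.asarray(dists, dtype=float))
    cdf = np.arange(1, d.size + 1) / d.size if d.size else np.empty(0)
    return pd.DataFrame({"distance": d, "cum_fraction": cdf})


# ---------------------------------------------------------------------------
# hypothesis tests


def stat_tests(data, test: str, **options) -> tuple[float, float]:
    """Two-sided tests with the conventions used throughout the analysis.

    fisher: 2x2 count table, exact two-sided.  wilcoxon: two-sample
    rank-sum, normal approximation with continuity correction.  ttest:
    Welch two-sample.  ks: two-sample Kolmogorov-Smirnov.  Returns
    (statistic, p-value).
    """
    if test == "fisher":
        table = np.asarray(data)
        if table.shape != (2, 2):
            raise ValueError("fisher requires a 2x2 table")
        if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
            raise ValueError("fisher table has a zero margin")
        res = stats.fisher_exact(table, alternative="two-sided")
        return float(res[0]), float(res[1])
    x, y = (np.asarray(a, dtype=float) for a in data)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    if test == "wilcoxon":
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", use_continuity=True,
            method=options.get("method", "asymptotic"),
        )
    elif test == "ttest":
        res = stats.ttest_ind(x, y, equal_var=False)
    elif test == "ks":
        res = stats.ks_2samp(x, y, method=options.get("method", "auto"))
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)


def adjust_pvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg false-discovery-rate adjustment."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# per-meiosis summaries


@dataclass
class MeiosisSummary:
    meiosis_id: str
    genotype: str = ""
    co_count: int = 0
    nco_count: int = 0
    complex_count: int = 0
    type_u_count: int = 0
    multi_dsb_counts: dict = field(default_factory=dict)
    trans_dsb_count: int = 0
    per_chrom_co: dict = field(default_factory=dict)
    nonexchange_zero_co: list = field(default_factory=list)
    nonexchange_zero_co_nco: list = field(default_factory=list)
    icds: np.ndarray = field(default_factory=lambda: np.empty(0))
    midlengths_co: list = field(default_factory=list)
    midlengths_nco: list = field(default_factory=list)

    @property
    def total_events(self) -> int:
        return self.co_count + self.nco_count


def summarize_meiosis(
    meiosis_id: str,
    events: list[RecombinationEvent],
    genome: GenomeModel,
    genotype: str = "",
) -> MeiosisSummary:
    """Tally one classified meiosis.

    Type-U events are excluded from CO/NCO tallies (they cannot be
    classified); multi-DSB events are excluded from the mid-length lists.
    Non-exchange chromosomes are reported both as zero-CO (the simulation's
    definition) and as the stricter zero-CO-and-NCO.
    """
    s = MeiosisSummary(meiosis_id=meiosis_id, genotype=genotype)
    s.multi_dsb_counts = {c: 0 for c in ("dCO", "dNCO_sister", "dNCO_overlap", "CO_plus_NCO")}
    s.per_chrom_co = {c: 0 for c in genome.names}
    nco_chroms: set[str] = set()
    for ev in events:
        if ev.type_u:
            s.type_u_count += 1
            continue
        s.co_count += ev.co_count
        s.nco_count += ev.nco_count
        if ev.complex_flag:
            s.complex_count += 1
        s.per_chrom_co[ev.chrom] = s.per_chrom_co.get(ev.chrom, 0) + ev.co_count
        if ev.nco_count:
            nco_chroms.add(ev.chrom)
        cat = ev.category
        if cat is not None:
            if cat.multi_dsb != "none":
                s.multi_dsb_counts[cat.multi_dsb] += 1
            if cat.trans_dsb:
                s.trans_dsb_count += 1
            is_multi = cat.multi_dsb != "none"
        else:
            is_multi = False
        if not is_multi and ev.n_markers > 0:
            ml = event_midlength(ev)
            if ev.co_count:
                s.midlengths_co.append(ml)
            elif ev.nco_count:
                s.midlengths_nco.append(ml)
    s.nonexchange_zero_co = [c for c in genome.names if s.per_chrom_co.get(c, 0) == 0]
    s.nonexchange_zero_co_nco = [
        c for c in s.nonexchange_zero_co if c not in nco_chroms
    ]
    s.icds = compute_icds(co_positions_from_events(events))
    return s
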