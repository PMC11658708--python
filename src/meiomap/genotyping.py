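"""Genotype calling and octad/mocktad assembly.

Converts pileup-style allele counts into binary parental genotype calls
using fixed read-fraction thresholds, then assembles them into the 8 x
markers strand matrix the event caller consumes.  Three routes exist:

* true octads — eight post-meiotic mother/daughter samples, one per
  strand; heteroduplex calls are discarded (set MISSING);
* MMR-proficient tetrads — four spores duplicated into strand pairs;
* MMR-deficient tetrads ("mocktads") — four whole-colony samples whose
  mixed-read (heteroduplex) calls are split into a mother/daughter strand
  pair with an arbitrary global polarity (mother -> variant parent,
  daughter -> reference parent), optionally phased afterwards with a
  resequenced single colony.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import HET, MISSING, PARENT_A, PARENT_B, StrandMatrix

__all__ = [
    "CallerConfig",
    "call_genotype",
    "call_genotypes",
    "calls_to_matrices",
    "assemble_octad",
    "duplicate_tetrad",
    "build_mocktad",
    "phase_with_colony",
]


@dataclass(frozen=True)
class CallerConfig:
    """Thresholds of the read-fraction genotype caller (all >=-inclusive).

    ``het_balance_mode`` selects the reading of the heteroduplex balance
    rule ("the variant and reference reads ... within 70% of each other"):
    "ratio" (default) requires min(ref,var)/max(ref,var) >= 0.70, "diff"
    requires |ref - var| / depth <= 1 - 0.70.
    """

    min_depth: int = 5
    snp_var_thresh: float = 0.70
    snp_ref_thresh: float = 0.90
    het_combined_thresh: float = 0.90
    het_balance_thresh: float = 0.70
    het_balance_mode: str = "ratio"
    indel_var_thresh: float = 0.30
    indel_ref_thresh: float = 0.95
    indel_max_var_reads: int = 1
    recurrent_het_cutoff: int = 2     # markers HET in more than this many samples are dropped

    def __post_init__(self) -> None:
        for name in (
            "snp_var_thresh", "snp_ref_thresh", "het_combined_thresh",
            "het_balance_thresh", "indel_var_thresh", "indel_ref_thresh",
        ):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if self.het_balance_mode not in ("ratio", "diff"):
            raise ValueError("het_balance_mode must be 'ratio' or 'diff'")


def call_genotype(
    n_ref: int, n_var: int, n_other: int, depth: int, kind: str,
    cfg: CallerConfig = CallerConfig(),
) -> int:
    """Call one site: PARENT_A (1), PARENT_B (0), HET (2) or MISSING (-1).

    SNPs: variant if var/depth >= 0.70, else reference if ref/depth >=
    0.90, else heteroduplex if (ref+var)/depth >= 0.90 and the two counts
    are balanced, else missing.  Indels: variant if var/depth >= 0.30;
    reference requires ref/depth >= 0.95 *and* fewer than two variant
    reads; indels are never called heteroduplex.
    """
    if kind not in ("SNP", "insertion", "deletion"):
        raise ValueError(f"unknown marker kind {kind!r}")
    if depth < cfg.min_depth:
        return MISSING
    if kind == "SNP":
        if n_var / depth >= cfg.snp_var_thresh:
            return PARENT_B
        if n_ref / depth >= cfg.snp_ref_thresh:
            return PARENT_A
        if (n_ref + n_var) / depth >= cfg.het_combined_thresh:
            if cfg.het_balance_mode == "ratio":
                lo, hi = min(n_ref, n_var), max(n_ref, n_var)
                balanced = hi > 0 and lo / hi >= cfg.het_balance_thresh
            else:
                balanced = abs(n_ref - n_var) / depth <= 1.0 - cfg.het_balance_thresh
            if balanced:
                return HET
        return MISSING
    # indel
    if n_var / depth >= cfg.indel_var_thresh:
        return PARENT_B
    if n_ref / depth >= cfg.indel_ref_thresh and n_var <= cfg.indel_max_var_reads:
        return PARENT_A
    return MISSING


def call_genotypes(counts: pd.DataFrame, cfg: CallerConfig = CallerConfig()) -> pd.Series:
    """Vectorised caller over a counts frame with a ``kind`` column.

    Returns an int8 Series aligned with ``counts``.
    """
    depth = counts["depth"].to_numpy(dtype=np.int64)
    n_ref = counts["n_ref"].to_numpy(dtype=np.int64)
    n_var = counts["n_var"].to_numpy(dtype=np.int64)
    is_snp = (counts["kind"] == "SNP").to_numpy()
    d = np.maximum(depth, 1)
    out = np.full(len(counts), MISSING, dtype=np.int8)

    var_f = n_var / d
    ref_f = n_ref / d
    lo = np.minimum(n_ref, n_var)
    hi = np.maximum(n_ref, n_var)
    if cfg.het_balance_mode == "ratio":
        balanced = (hi > 0) & (lo >= cfg.het_balance_thresh * hi)
    else:
        balanced = np.abs(n_ref - n_var) / d <= 1.0 - cfg.het_balance_thresh
    het_ok = is_snp & ((n_ref + n_var) / d >= cfg.het_combined_thresh) & balanced
    snp_b = is_snp & (var_f >= cfg.snp_var_thresh)
    snp_a = is_snp & ~snp_b & (ref_f >= cfg.snp_ref_thresh)
    snp_h = is_snp & ~snp_b & ~snp_a & het_ok
    ind_b = ~is_snp & (var_f >= cfg.indel_var_thresh)
    ind_a = (
        ~is_snp & ~ind_b
        & (ref_f >= cfg.indel_ref_thresh)
        & (n_var <= cfg.indel_max_var_reads)
    )
    out[snp_b | ind_b] = PARENT_B
    out[snp_a | ind_a] = PARENT_A
    out[snp_h] = HET
    out[depth < cfg.min_depth] = MISSING
    return pd.Series(out, index=counts.index, name="call")


def calls_to_matrices(
    counts: pd.DataFrame,
    marker_map: pd.DataFrame,
    samples: list[str],
    cfg: CallerConfig = CallerConfig(),
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Pivot per-site calls into per-chromosome (positions, S x n call) arrays.

    Markers of the map absent from a sample's counts are MISSING for that
    sample.  Sample order follows ``samples`` (row order of the result).
    """
    merged = counts.merge(
        marker_map[["chrom", "pos", "kind"]], on=["chrom", "pos"], how="inner"
    )
    merged["call"] = call_genotypes(merged, cfg)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, cmap in marker_map.groupby("chrom", sort=False):
        pos = cmap["pos"].to_numpy(dtype=np.int64)
        sub = merged[merged["chrom"] == chrom]
        wide = sub.pivot_table(
            index="pos", columns="sample", values="call", aggfunc="first"
        )
        calls = np.full((len(samples), pos.size), MISSING, dtype=np.int8)
        if len(wide):
            idx = np.searchsorted(pos, wide.index.to_numpy())
            for i, s in enumerate(samples):
                if s in wide.columns:
                    col = wide[s].to_numpy()
                    valid = ~np.isnan(col)
                    calls[i, idx[valid]] = col[valid].astype(np.int8)
        out[chrom] = (pos, calls)
    return out


def assemble_octad(
    calls: np.ndarray, positions: np.ndarray, chrom: str
) -> StrandMatrix:
    """Assemble 8 per-strand call vectors into a strand matrix.

    Rows must already be ordered as mother/daughter pairs.  Heteroduplex
    calls in a true octad are spurious (each sample is a single strand)
    and are discarded as MISSING; columns containing any MISSING strand
    are flagged by the matrix and later bridged by segmentation.
    """
    calls = np.asarray(calls, dtype=np.int8)
    if calls.shape[0] != 8:
        raise ValueError(f"octad requires 8 samples, got {calls.shape[0]}")
    geno = calls.copy()
    geno[geno == HET] = MISSING
    return StrandMatrix(chrom=chrom, positions=positions, geno=geno)


def duplicate_tetrad(
    calls: np.ndarray, positions: np.ndarray, chrom: str
) -> StrandMatrix:
    """MMR-proficient tetrad: duplicate each spore into a concordant pair.

    Heteroduplex calls (impossible in an MMR-proficient spore) are
    discarded; only even segregation patterns can arise.
    """
    calls = np.asarray(calls, dtype=np.int8)
    if calls.shape[0] != 4:
        raise ValueError(f"tetrad requires 4 samples, got {calls.shape[0]}")
    geno = np.repeat(calls, 2, axis=0)
    geno[geno == HET] = MISSING
    return StrandMatrix(chrom=chrom, positions=positions, geno=geno)


def build_mocktad(
    calls: np.ndarray,
    positions: np.ndarray,
    chrom: str,
    cfg: CallerConfig = CallerConfig(),
) -> StrandMatrix:
    """Reconstruct a pseudo-octad from an MMR-deficient tetrad.

    Each spore is duplicated into a mother/daughter strand pair;
    heteroduplex calls are split mother -> variant parent, daughter ->
    reference parent (the arbitrary global polarity), and the spore is
    flagged "polarity unknown".  Markers heteroduplex in more than
    ``cfg.recurrent_het_cutoff`` samples are eliminated as presumed
    marker-table errors.
    """
    calls = np.asarray(calls, dtype=np.int8)
    if calls.shape[0] != 4:
        raise ValueError(f"mocktad requires 4 samples, got {calls.shape[0]}")
    keep = (calls == HET).sum(axis=0) <= cfg.recurrent_het_cutoff
    calls = calls[:, keep]
    positions = np.asarray(positions)[keep]
    geno = np.repeat(calls, 2, axis=0)
    het_mask = calls == HET
    for spore in range(4):
        m = het_mask[spore]
        geno[2 * spore, m] = PARENT_B      # arbitrary polarity: mother -> SK1-like
        geno[2 * spore + 1, m] = PARENT_A  # daughter -> S288c-like
    polarity = np.array([not het_mask[s].any() for s in range(4)])
    return StrandMatrix(
        chrom=chrom,
        positions=positions,
        geno=geno,
        polarity_known=polarity,
        het_mask=het_mask,
    )


def phase_with_colony(
    mocktad: StrandMatrix,
    spore: int,
    colony_calls: np.ndarray,
    strand: str = "mother",
) -> tuple[StrandMatrix, int]:
    """Resolve the mother/daughter polarity of one mocktad spore.

    ``colony_calls`` are the genotype calls of a restreaked single colony
    (one post-meiotic strand of the spore), aligned with the mocktad's
    marker set.  At each formerly heteroduplex marker the colony's call is
    assigned to the declared strand and the complementary parental call to
    the other; markers where the colony is itself heteroduplex or missing
    keep the arbitrary polarity.  Returns the phased matrix and the number
    of unresolved heteroduplex markers (the polarity flag is cleared only
    when it is zero).
    """
    if mocktad.het_mask is None:
        raise ValueError("matrix does not carry heteroduplex provenance; not a mocktad")
    if not 0 <= spore <= 3:
        raise ValueError("spore index must be 0-3")
    if strand not in ("mother", "daughter"):
        raise ValueError("strand must be 'mother' or 'daughter'")
    colony_calls = np.asarray(colony_calls, dtype=np.int8)
    if colony_calls.size != mocktad.n_markers:
        raise ValueError("colony calls must align with the mocktad marker set")
    out = mocktad.copy()
    targets = np.flatnonzero(mocktad.het_mask[spore])
    unresolved = 0
    own = 2 * spore if strand == "mother" else 2 * spore + 1
    other = 2 * spore + 1 if strand == "mother" else 2 * spore
    for i in targets:
        c = int(colony_calls[i])
        if c in (PARENT_A, PARENT_B):
            out.geno[own, i] = c
            out.geno[other, i] = 1 - c
        else:
            unresolved += 1
    if unresolved == 0:
        out.polarity_known[spore] = True
    return out, unresolved
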