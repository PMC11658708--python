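"""Hand-built strand matrices transcribing the canonical event panels.

Each builder returns (StrandMatrix, expected) where ``expected`` is a
dict of the category fields the event must receive.  Conventions:
markers every 100 bp starting at 1,000; chromatids 0-1 begin the
chromosome as parent A (value 1) and chromatids 2-3 as parent B (0);
row 2k is the mother strand and row 2k+1 the daughter strand of
chromatid k.  Ten Mendelian markers flank the event region on each side
(> 1.5 kb of 4:4), so every matrix carries exactly one callable event.
"""

from __future__ import annotations

import numpy as np

from meiomap.matrix import StrandMatrix

A, B = 1, 0
N = 40            # markers per panel chromosome
SPACING = 100


def base_matrix(chrom: str = "chrPanel") -> StrandMatrix:
    pos = 1000 + SPACING * np.arange(N)
    geno = np.empty((8, N), dtype=np.int8)
    geno[0:4] = A
    geno[4:8] = B
    return StrandMatrix(chrom=chrom, positions=pos, geno=geno)


def _co(sm: StrandMatrix, k1: int, k2: int, col: int) -> None:
    """Reciprocal arm exchange between chromatids k1, k2 from ``col`` on."""
    r1 = [2 * k1, 2 * k1 + 1]
    r2 = [2 * k2, 2 * k2 + 1]
    tmp = sm.geno[r1, col:].copy()
    sm.geno[r1, col:] = sm.geno[r2, col:]
    sm.geno[r2, col:] = tmp


def _het(sm: StrandMatrix, k: int, cols, allele: int, strand: str = "daughter") -> None:
    row = 2 * k + (1 if strand == "daughter" else 0)
    sm.geno[row, cols] = allele


def _full(sm: StrandMatrix, k: int, cols, allele: int) -> None:
    sm.geno[2 * k: 2 * k + 2, cols] = allele


# ---------------------------------------------------------------------------
# multi-DSB panels (double NCOs, double CO, CO+NCO, trans-DSB patterns)


def dnco_sister():
    sm = base_matrix()
    _het(sm, 0, slice(12, 15), B)           # NCO tract on chromatid 0
    _het(sm, 1, slice(17, 20), B)           # second tract on its sister
    return sm, {"multi_dsb": "dNCO_sister", "co_count": 0, "nco_count": 2}


def dnco_overlap():
    sm = base_matrix()
    _full(sm, 0, slice(13, 18), B)          # perfectly overlapping conversions
    _full(sm, 2, slice(13, 18), A)          # on two homologues
    return sm, {"multi_dsb": "dNCO_overlap", "co_count": 0, "nco_count": 2}


def dco():
    sm = base_matrix()
    _co(sm, 0, 2, 13)                       # double reciprocal exchange
    _co(sm, 1, 3, 17)                       # affecting all four chromatids
    return sm, {"multi_dsb": "dCO", "co_count": 2, "nco_count": 0}


def co_plus_nco():
    sm = base_matrix()
    _co(sm, 1, 2, 14)
    _het(sm, 3, slice(15, 18), A)           # conversion on a third chromatid
    return sm, {"multi_dsb": "CO_plus_NCO", "co_count": 1, "nco_count": 1}


def co_plus_nco_71():
    sm = base_matrix()
    _co(sm, 1, 2, 14)
    _full(sm, 1, slice(12, 14), B)          # full conversion beside the exchange
    _het(sm, 0, slice(12, 14), B)           # plus hDNA on the sister: 1:7
    return sm, {"multi_dsb": "CO_plus_NCO", "trans_dsb": True, "co_count": 1}


def dnco_sister_80():
    sm = base_matrix()
    _het(sm, 0, slice(12, 14), B)           # hDNA stub
    _full(sm, 0, slice(14, 17), B)          # gap repair on both sisters:
    _full(sm, 1, slice(14, 17), B)          # 0:8 segregation inside
    _het(sm, 1, slice(17, 19), B)
    return sm, {"multi_dsb": "dNCO_sister", "trans_dsb": True}


def dnco_sister_71():
    sm = base_matrix()
    _full(sm, 0, slice(13, 17), B)          # full conversion on one sister
    _het(sm, 1, slice(15, 18), B)           # hDNA on the other: 1:7 overlap
    return sm, {"multi_dsb": "dNCO_sister", "trans_dsb": True}


# ---------------------------------------------------------------------------
# noncrossover panels


def nco_full_conversion():
    sm = base_matrix()
    _full(sm, 0, slice(13, 17), B)
    return sm, {"nco_class": "full_conversion", "co_count": 0, "nco_count": 1}


def nco_one_sided():
    sm = base_matrix()
    _het(sm, 0, slice(13, 17), B)
    return sm, {"nco_class": "one_sided", "co_count": 0, "nco_count": 1}


def nco_one_sided_patch():
    sm = base_matrix()
    _het(sm, 0, slice(12, 18), B)
    _full(sm, 0, slice(14, 16), B)          # internal full-conversion patch
    return sm, {"nco_class": "one_sided_patch"}


def nco_two_sided_trans():
    sm = base_matrix()
    _het(sm, 0, slice(12, 15), B, "daughter")
    _het(sm, 0, slice(15, 18), B, "mother")  # opposite polarity, same chromatid
    return sm, {"nco_class": "two_sided_trans"}


def nco_two_sided_restoration():
    sm = base_matrix()
    _het(sm, 0, slice(11, 14), B)
    _het(sm, 0, slice(16, 19), B)           # separated by a 4:4 restoration tract
    return sm, {"nco_class": "two_sided_restoration"}


def nco_two_chromatid():
    sm = base_matrix()
    _het(sm, 0, slice(12, 16), B)           # partial overlap on two
    _het(sm, 2, slice(14, 18), A)           # non-sister chromatids
    return sm, {"nco_class": "two_chromatid", "multi_dsb": "none"}


# ---------------------------------------------------------------------------
# crossover panels


def co_no_transfer():
    sm = base_matrix()
    _co(sm, 1, 2, 15)
    return sm, {"co_class": "no_strand_transfer", "co_count": 1}


def co_full_conversion():
    sm = base_matrix()
    _co(sm, 1, 2, 15)
    _full(sm, 1, slice(12, 15), B)          # single full-conversion tract
    return sm, {"co_class": "full_conversion", "co_count": 1}


def co_one_sided_uni():
    sm = base_matrix()
    _co(sm, 1, 2, 15)
    _het(sm, 1, slice(12, 15), B)           # one hDNA tract, one donor
    return sm, {"co_class": "one_sided_unidirectional", "co_count": 1}


def co_one_sided_bi():
    sm = base_matrix()
    # junction migration: chromatid 1 heteroduplex across the exchange,
    # chromatid 2 switching mid-tract, so converted markers derive from
    # both parents within a single tract
    _co(sm, 1, 2, 15)
    sm.geno[2, 13:17] = A                   # mother strand of chromatid 1
    sm.geno[3, 13:17] = B                   # daughter strand
    return sm, {"co_class": "one_sided_bidirectional", "co_count": 1}


def co_two_sided_uni():
    sm = base_matrix()
    _co(sm, 1, 2, 15)
    _het(sm, 1, slice(12, 15), B)           # trans hDNA on the two recombining
    _het(sm, 2, slice(15, 18), B)           # chromatids, single donor
    return sm, {"co_class": "two_sided_unidirectional", "co_count": 1}


def co_two_sided_bi():
    sm = base_matrix()
    _co(sm, 1, 2, 15)
    _het(sm, 1, slice(12, 15), B)           # trans hDNA on one chromatid only,
    _het(sm, 1, slice(15, 18), A)           # donors from both parents
    return sm, {"co_class": "two_sided_bidirectional", "co_count": 1}


def co_symmetric_hdna():
    sm = base_matrix()
    _co(sm, 1, 2, 15)
    _het(sm, 1, slice(13, 15), B, "daughter")   # symmetric hDNA: 4:4* columns
    _het(sm, 2, slice(13, 15), A, "daughter")
    return sm, {"co_class": "symmetric_hDNA", "co_count": 1}


ALL_PANELS = {
    "dNCO_sister": dnco_sister,
    "dNCO_nonsister_overlap": dnco_overlap,
    "dCO": dco,
    "CO_plus_NCO_third_chromatid": co_plus_nco,
    "CO_plus_NCO_with_7_1": co_plus_nco_71,
    "dNCO_sister_with_8_0": dnco_sister_80,
    "dNCO_sister_with_7_1": dnco_sister_71,
    "NCO_full_conversion": nco_full_conversion,
    "NCO_one_sided": nco_one_sided,
    "NCO_one_sided_patch": nco_one_sided_patch,
    "NCO_two_sided_trans": nco_two_sided_trans,
    "NCO_two_sided_restoration": nco_two_sided_restoration,
    "NCO_two_chromatid": nco_two_chromatid,
    "CO_no_strand_transfer": co_no_transfer,
    "CO_full_conversion": co_full_conversion,
    "CO_one_sided_unidirectional": co_one_sided_uni,
    "CO_one_sided_bidirectional": co_one_sided_bi,
    "CO_two_sided_unidirectional": co_two_sided_uni,
    "CO_two_sided_bidirectional": co_two_sided_bi,
    "CO_symmetric_hDNA": co_symmetric_hdna,
}
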