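"""Segregation patterns, segmentation, event grouping and CO counting."""

import numpy as np
import pytest

from meiomap.events import (
    call_events,
    classify_column,
    count_crossovers,
    segment_chromosome,
)
from meiomap.matrix import MISSING, PARENT_A, PARENT_B, StrandMatrix
from meiomap.pipeline import analyze_matrices
from meiomap.simdata import SimParams, simulate_meiosis
from panels import base_matrix, _het

A, B = PARENT_A, PARENT_B


def brute_force_segments(geno, positions):
    """Independent run-length oracle: python loop, column-by-column."""
    keep = [i for i in range(positions.size) if all(geno[r, i] != MISSING for r in range(8))]
    runs = []
    for i in keep:
        col = tuple(geno[:, i])
        if runs and runs[-1][0] == col:
            runs[-1][1].append(i)
        else:
            runs.append((col, [i]))
    out = []
    for col, idxs in runs:
        n_a = sum(1 for v in col if v == A)
        disc = sum(1 for k in range(4) if col[2 * k] != col[2 * k + 1])
        out.append((positions[idxs[0]], positions[idxs[-1]], n_a, disc))
    return out


class TestClassifyColumn:
    def test_parental_4_4_is_mendelian(self):
        col = np.array([A, A, A, A, B, B, B, B])
        p = classify_column(col, parental=col)
        assert p.ratio == "4:4" and p.label == "MENDELIAN"

    def test_single_heteroduplex_pair_is_5_3(self):
        p = classify_column(np.array([A, A, A, A, A, B, B, B]))
        assert p.ratio == "5:3" and p.label == "HALF_CONVERSION"

    def test_two_trans_half_conversions_are_6_2_star(self):
        p = classify_column(np.array([A, A, A, A, A, B, A, B]))
        assert p.ratio == "6:2*" and p.label == "TRANS"

    def test_full_conversion_6_2_not_starred(self):
        p = classify_column(np.array([A, A, A, A, A, A, B, B]))
        assert p.ratio == "6:2" and p.label == "FULL_CONVERSION"

    def test_symmetric_hdna_4_4_star(self):
        p = classify_column(np.array([A, A, A, B, B, A, B, B]))
        assert p.ratio == "4:4*" and p.label == "SYMMETRIC"

    def test_rearranged_concordant_4_4_starred_against_parental(self):
        parental = np.array([A, A, A, A, B, B, B, B])
        rearranged = np.array([B, B, A, A, A, A, B, B])
        assert classify_column(rearranged, parental=parental).star
        assert not classify_column(rearranged).star

    def test_missing_rejected(self):
        with pytest.raises(ValueError):
            classify_column(np.array([A, A, A, A, B, B, B, MISSING]))


class TestSegmentation:
    def test_all_parental_single_segment(self):
        sm = base_matrix()
        seg = segment_chromosome(sm)
        assert len(seg.segments) == 1
        s = seg.segments[0]
        assert s.start_idx == 0 and s.end_idx == sm.n_markers - 1
        assert s.pattern.is_mendelian

    def test_single_conversion_gives_three_segments(self):
        sm = base_matrix()
        _het(sm, 0, slice(8, 13), B)
        seg = segment_chromosome(sm)
        ratios = [s.pattern.ratio for s in seg.segments]
        assert ratios == ["4:4", "3:5", "4:4"]

    def test_random_matrices_match_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = 20
            geno = rng.choice(
                [A, B, MISSING], size=(8, n), p=[0.45, 0.45, 0.1]
            ).astype(np.int8)
            pos = np.sort(rng.choice(np.arange(1, 10_000), size=n, replace=False))
            sm = StrandMatrix(chrom="c", positions=pos, geno=geno)
            seg = segment_chromosome(sm)
            got = [
                (s.start_pos, s.end_pos, s.pattern.n_a, s.pattern.n_discordant)
                for s in seg.segments
            ]
            assert got == brute_force_segments(geno, pos)

    def test_segments_partition_retained_markers(self):
        rng = np.random.default_rng(1)
        geno = rng.choice([A, B], size=(8, 100)).astype(np.int8)
        sm = StrandMatrix(chrom="c", positions=np.arange(1, 101) * 50, geno=geno)
        seg = segment_chromosome(sm)
        covered = []
        for s in seg.segments:
            covered.extend(range(s.start_idx, s.end_idx + 1))
        assert covered == list(range(100))
        for s1, s2 in zip(seg.segments, seg.segments[1:]):
            assert not np.array_equal(s1.vector, s2.vector)


class TestCallEvents:
    def test_distant_patches_are_two_events(self):
        sm = base_matrix()           # markers every 100 bp
        _het(sm, 0, slice(5, 7), B)
        _het(sm, 0, slice(30, 32), B)   # 2.3 kb of 4:4 between
        events = call_events(segment_chromosome(sm))
        assert len(events) == 2

    def test_sub_threshold_gap_merges_into_one_event_with_restoration(self):
        sm = base_matrix()
        _het(sm, 0, slice(5, 7), B)
        _het(sm, 0, slice(15, 17), B)   # 0.9 kb of 4:4 between
        events = call_events(segment_chromosome(sm))
        assert len(events) == 1
        assert any(s.pattern.is_mendelian for s in events[0].segments)

    def test_threshold_is_at_least_1500(self):
        # flanking-marker distance exactly 1500 bp separates ("at least 1.5 kb")
        sm = base_matrix()
        _het(sm, 0, slice(5, 7), B)     # last anomaly marker at 1600
        _het(sm, 0, slice(21, 23), B)   # first anomaly marker at 3100
        events = call_events(segment_chromosome(sm))
        assert len(events) == 2

    def test_conversion_into_telomere_is_type_u(self):
        sm = base_matrix()
        _het(sm, 0, slice(35, 40), B)   # runs to the last marker
        events = call_events(segment_chromosome(sm))
        assert len(events) == 1
        assert events[0].type_u

    def test_marker_desert_inside_event_does_not_split_it(self):
        # two touching non-Mendelian segments with no 4:4 marker between
        # must remain one event even when they are > 1.5 kb apart
        pos = np.concatenate([np.arange(20) * 100 + 1000,
                              [5000, 5100, 5200],
                              np.arange(20) * 100 + 9000])
        geno = np.empty((8, pos.size), dtype=np.int8)
        geno[0:4] = A
        geno[4:8] = B
        geno[1, 18:20] = B     # 5:3 up to pos 2900
        geno[1, 20:23] = B     # continues at pos 5000 with a different strand
        geno[0, 20:23] = B     # vector change: 6:2-ish
        sm = StrandMatrix(chrom="c", positions=pos, geno=geno)
        events = call_events(segment_chromosome(sm))
        assert len(events) == 1

    def test_min_gap_monotonicity(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            sm = base_matrix()
            for _k in range(4):
                k = int(rng.integers(0, 4))
                s = int(rng.integers(0, 35))
                _het(sm, k, slice(s, s + int(rng.integers(1, 5))), B if k < 2 else A)
            seg = segment_chromosome(sm)
            counts = [len(call_events(seg, min_gap_bp=g)) for g in (200, 1500, 5000)]
            assert counts[0] >= counts[1] >= counts[2]


class TestCountCrossovers:
    def test_single_reciprocal_exchange(self):
        left = np.array([A, A, A, A, B, B, B, B])
        right = np.array([A, A, B, B, A, A, B, B])
        co, changed, irregular = count_crossovers(left, right)
        assert co == 1 and changed == [1, 2] and not irregular

    def test_identical_flanks_zero_co(self):
        left = np.array([A, A, A, A, B, B, B, B])
        co, changed, irregular = count_crossovers(left, left)
        assert co == 0 and not changed and not irregular

    def test_four_chromatid_double_exchange(self):
        left = np.array([A, A, A, A, B, B, B, B])
        right = np.array([B, B, B, B, A, A, A, A])
        co, changed, irregular = count_crossovers(left, right)
        assert co == 2 and len(changed) == 4 and not irregular

    def test_odd_change_flagged_irregular(self):
        left = np.array([A, A, A, A, B, B, B, B])
        right = np.array([B, B, A, A, B, B, B, B])
        co, changed, irregular = count_crossovers(left, right)
        assert irregular and co == 0

    def test_internal_conversion_zero_co_one_nco(self):
        sm = base_matrix()
        sm.geno[0:2, 13:17] = B   # 6:2 tract, flanks unchanged
        events = call_events(segment_chromosome(sm))
        assert len(events) == 1
        assert events[0].co_count == 0
        assert list(events[0].nco_runs) == [0]


class TestEventSpans:
    def test_called_spans_contain_planted_dsbs(self, marker_map, genome):
        params = SimParams(seed=21, mean_co=60.0, nco_co_ratio=0.0,
                           multi_dsb_rate=0.0, min_event_sep=7000.0)
        mats, truth = simulate_meiosis(marker_map, genome, params)
        events = analyze_matrices(mats)
        by_chrom = {}
        for ev in events:
            by_chrom.setdefault(ev.chrom, []).append(ev)
        pad = 200   # one marker spacing of slack at the span edge
        n_checked = 0
        for pe in truth.events:
            x = pe.dsb_positions[0]
            hits = [
                e for e in by_chrom.get(pe.chrom, [])
                if e.start_pos - pad <= x <= e.end_pos + pad and not e.type_u
            ]
            assert hits, f"planted CO at {pe.chrom}:{x} not covered"
            n_checked += 1
        assert n_checked > 30

    def test_per_chromosome_co_counts_match_planted_truth(self, clean_meiosis):
        mats, truth = clean_meiosis
        events = analyze_matrices(mats)
        called = {}
        for ev in events:
            if not ev.type_u:
                called[ev.chrom] = called.get(ev.chrom, 0) + ev.co_count
        planted = truth.co_counts_per_chrom()
        for chrom in mats:
            assert called.get(chrom, 0) == planted.get(chrom, 0)
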