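"""Spatial statistics: lengths, assurance null, gamma/ICD, tests, BH."""

import numpy as np
import pytest
from scipy import stats

from meiomap.genome import GenomeModel
from meiomap.meiostats import (
    NonExchangeSim,
    adjust_pvalues,
    aggregate_nonexchange,
    co_positions_from_events,
    compute_icds,
    distance_to_feature_cdf,
    event_midlength,
    fit_gamma_mle,
    homeostasis_trend,
    length_quartiles,
    nonexchange_pvalue,
    random_icd_reference,
    simulate_nonexchange,
    stat_tests,
    summarize_meiosis,
)
from meiomap.pipeline import analyze_matrices
from panels import ALL_PANELS, _het, base_matrix
from meiomap.matrix import PARENT_B


class TestMidlength:
    def _event_with_markers(self, first, last):
        # markers every 100 bp from 1000; event tract on the given columns
        sm = base_matrix()
        _het(sm, 0, slice(first, last + 1), PARENT_B)
        events = analyze_matrices({sm.chrom: sm})
        assert len(events) == 1
        return events[0]

    def test_formula_midpoints_of_flanking_intervals(self):
        # event markers at 2000..2500, flanks at 1900 and 2600:
        # (2500+2600)/2 - (1900+2000)/2 = 600
        ev = self._event_with_markers(10, 15)
        assert event_midlength(ev) == pytest.approx(600.0)

    def test_single_marker_event(self):
        # flanks 100 bp either side: mid-length = one marker spacing
        ev = self._event_with_markers(12, 12)
        assert event_midlength(ev) == pytest.approx(100.0)

    def test_type_u_undefined(self):
        sm = base_matrix()
        _het(sm, 0, slice(35, 40), PARENT_B)
        ev = analyze_matrices({sm.chrom: sm})[0]
        assert ev.type_u
        with pytest.raises(ValueError):
            event_midlength(ev)

    def test_midlength_tracks_planted_tract_extent(self, clean_meiosis):
        mats, truth = clean_meiosis
        events = analyze_matrices(mats)
        by_chrom = {}
        for ev in events:
            by_chrom.setdefault(ev.chrom, []).append(ev)
        errors = []
        for pe in truth.events:
            if pe.kind != "NCO":
                continue
            lo, hi = pe.span
            hits = [
                e for e in by_chrom.get(pe.chrom, [])
                if not e.type_u and e.start_pos <= hi and e.end_pos >= lo
                and e.co_count == 0
            ]
            if len(hits) == 1:
                errors.append(event_midlength(hits[0]) - (hi - lo))
        assert len(errors) > 10
        # mid-length unbiased to within about one inter-marker spacing
        assert abs(np.mean(errors)) < 200


class TestQuartiles:
    def test_median_of_five(self):
        q1, med, q3 = length_quartiles([1e3, 2e3, 3e3, 4e3, 5e3])
        assert med == 3e3

    def test_degenerate_all_equal(self):
        q1, med, q3 = length_quartiles([7.0] * 9)
        assert q1 == med == q3 == 7.0

    def test_large_sample_matches_distribution_quantiles(self):
        rng = np.random.default_rng(0)
        x = rng.gamma(2.0, 1000.0, size=20_000)
        q1, med, q3 = length_quartiles(x)
        d = stats.gamma(2.0, scale=1000.0)
        for got, q in [(q1, 0.25), (med, 0.5), (q3, 0.75)]:
            assert abs(got - d.ppf(q)) / d.ppf(q) < 0.03

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            length_quartiles([])


class TestNonExchange:
    def test_sixteen_equal_chromosomes_one_co(self):
        counts = simulate_nonexchange(np.full(16, 1 / 16), 1, 500, seed=0)
        assert (counts == 15).all()

    def test_single_chromosome_never_nonexchange(self):
        counts = simulate_nonexchange(np.array([1.0]), 5, 200, seed=0)
        assert (counts == 0).all()

    def test_mean_matches_closed_form(self, genome):
        p = genome.probabilities
        for n in (10, 90):
            counts = simulate_nonexchange(genome, n, 10_000, seed=3)
            analytic = np.sum((1 - p) ** n)
            se = counts.std(ddof=1) / np.sqrt(counts.size)
            assert abs(counts.mean() - analytic) <= 3 * max(se, 1e-9)

    def test_tail_probabilities(self, genome):
        sim = NonExchangeSim(genome, replicates=2000, seed=1)
        assert nonexchange_pvalue(0, 90, sim, "greater") == 1.0
        assert nonexchange_pvalue(17, 90, sim, "greater") == 0.0
        assert nonexchange_pvalue(16, 90, sim, "lesser") == 1.0
        eq = NonExchangeSim(np.full(16, 1 / 16), replicates=500, seed=2)
        assert nonexchange_pvalue(15, 1, eq, "greater") == 1.0

    def test_tail_monotone_in_k(self, genome):
        sim = NonExchangeSim(genome, replicates=2000, seed=5)
        probs = [sim.tail_probability(k, 60, "greater") for k in range(6)]
        assert all(a >= b for a, b in zip(probs, probs[1:]))

    def test_grid_bounds_enforced(self, genome):
        sim = NonExchangeSim(genome, replicates=100, seed=0)
        with pytest.raises(ValueError):
            sim.tail_probability(0, 201, "greater")
        ext = NonExchangeSim(genome, replicates=100, seed=0, extend=True)
        assert 0.0 <= ext.tail_probability(0, 300, "greater") <= 1.0

    def test_aggregation_is_median_to_the_power_n(self):
        assert aggregate_nonexchange([0.5]) == 0.5
        assert aggregate_nonexchange([0.5, 0.5, 0.5]) == pytest.approx(0.125)
        rng = np.random.default_rng(0)
        probs = rng.random(7)
        agg = aggregate_nonexchange(probs)
        assert 0.0 <= agg <= np.median(probs)


class TestICDs:
    def test_successive_distances(self):
        icds = compute_icds({"c": [100_000, 300_000, 350_000]})
        assert sorted(icds) == [50_000, 200_000]

    def test_single_co_chromosomes_contribute_nothing(self):
        assert compute_icds({f"c{i}": [1000.0] for i in range(16)}).size == 0

    def test_gamma_recovery(self):
        rng = np.random.default_rng(123)
        for shape in (1.0, 2.0):
            x = rng.gamma(shape, 40_000, size=10_000)
            fit = fit_gamma_mle(x)
            assert abs(fit.shape - shape) / shape < 0.05

    def test_mle_mean_identity(self):
        rng = np.random.default_rng(5)
        x = rng.gamma(1.7, 120_000, size=3000)
        fit = fit_gamma_mle(x)
        assert abs(fit.mean - x.mean()) / x.mean() < 1e-6

    def test_profile_fit_agrees_with_scipy(self):
        rng = np.random.default_rng(9)
        x = rng.gamma(2.5, 80_000, size=5000)
        fit = fit_gamma_mle(x)
        a, _, scale = stats.gamma.fit(x, floc=0)
        assert fit.shape == pytest.approx(a, rel=1e-4)
        assert fit.scale == pytest.approx(scale, rel=1e-4)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_gamma_mle([1.0] * 5)
        with pytest.raises(ValueError):
            fit_gamma_mle([1.0] * 9 + [-2.0])

    def test_near_constant_data_capped_with_warning(self, caplog):
        fit = fit_gamma_mle(np.full(50, 1000.0) + np.linspace(0, 1e-9, 50))
        assert fit.capped and fit.shape >= 1e5

    def test_reference_sample_mean_and_counts(self):
        ref = random_icd_reference(50_000.0, 20, n_cells=2000, seed=8)
        assert ref.size == 40_000
        se = ref.std() / np.sqrt(ref.size)
        assert abs(ref.mean() - 50_000) < 2.5 * se
        none = random_icd_reference(50_000.0, [0, 0, 3], n_cells=3, seed=1)
        assert none.size == 3   # zero-event cells contribute nothing

    def test_reference_is_exponential(self):
        ref = random_icd_reference(10_000.0, 50, n_cells=200, seed=3)
        _, p = stats.kstest(ref, "expon", args=(0, ref.mean()))
        assert p > 0.001


class TestHomeostasisAndDistance:
    def test_constant_ratio_zero_slope(self):
        slope, _ = homeostasis_trend([100, 150, 200], [50, 75, 100], [50, 75, 100])
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_two_point_slope(self):
        # ratios 2.0 at 100 events, 1.0 at 200 events -> slope -0.01
        slope, _ = homeostasis_trend([100, 200], [200, 200], [100, 200])
        assert slope == pytest.approx(-0.01)

    def test_fixed_co_varying_nco_gives_negative_slope(self):
        rng = np.random.default_rng(2)
        nco = rng.integers(30, 90, size=12)
        co = np.full(12, 60)
        slope, _ = homeostasis_trend(co + nco, co, nco)
        assert slope < 0

    def test_zero_nco_meioses_excluded(self):
        slope, _ = homeostasis_trend([100, 150, 200, 300], [50, 75, 100, 300],
                                     [50, 75, 100, 0])
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_telomere_distance_coordinates(self):
        g = GenomeModel(names=("c",), lengths=(1_000_000,), centromeres=(600_000,))
        df = distance_to_feature_cdf([("c", 5_000)], g, "telomere")
        assert df["distance"].iloc[0] == pytest.approx(4_999)
        df2 = distance_to_feature_cdf([("c", 600_000)], g, "centromere")
        assert df2["distance"].iloc[0] == 0.0

    def test_uniform_events_match_uniform_distance_null(self):
        g = GenomeModel(names=("c",), lengths=(1_000_000,))
        rng = np.random.default_rng(0)
        mids = rng.uniform(1, 1_000_000, size=4000)
        df = distance_to_feature_cdf({"c": mids}, g, "telomere")
        # distance to nearest end of a uniform point ~ U(0, L/2)
        _, p = stats.kstest(df["distance"], "uniform", args=(0, 500_000))
        assert p > 0.001


class TestStatTests:
    def test_fisher_extreme_table(self):
        _, p = stat_tests(np.array([[10, 0], [0, 10]]), "fisher")
        assert p < 1e-4

    def test_fisher_exact_oracle(self):
        # hypergeometric enumeration for a small table
        from scipy.stats import hypergeom

        table = np.array([[3, 7], [8, 2]])
        _, p = stat_tests(table, "fisher")
        n11 = np.arange(0, 11)
        pmf = hypergeom.pmf(n11, 20, 10, 11)
        expected = pmf[pmf <= pmf[3] * (1 + 1e-7)].sum()
        assert p == pytest.approx(expected, rel=1e-10)

    def test_ks_self_comparison(self):
        x = np.linspace(0, 1, 100)
        d, p = stat_tests((x, x), "ks")
        assert d == 0.0 and p == 1.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            stat_tests(np.array([[0, 0], [5, 5]]), "fisher")
        with pytest.raises(ValueError):
            stat_tests(([], [1.0, 2.0]), "wilcoxon")

    def test_bh_adjustment_worked_example(self):
        adj = adjust_pvalues([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_bh_properties(self):
        rng = np.random.default_rng(4)
        p = rng.random(50)
        adj = adjust_pvalues(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestSummaries:
    def test_meiosis_summary_tallies(self, genome):
        sm, _ = ALL_PANELS["CO_plus_NCO_third_chromatid"]()
        sm2, _ = ALL_PANELS["NCO_one_sided"]()
        sm2.chrom = "chrOther"
        events = analyze_matrices({sm.chrom: sm}) + analyze_matrices({sm2.chrom: sm2})
        s = summarize_meiosis("m1", events, genome)
        assert s.co_count == 1 and s.nco_count == 2
        assert s.multi_dsb_counts["CO_plus_NCO"] == 1
        # all 16 yeast chromosomes lack a CO except none of the panel ones
        assert len(s.nonexchange_zero_co) == 16

    def test_co_anchor_positions_resolve_double_co(self):
        sm, _ = ALL_PANELS["dCO"]()
        events = analyze_matrices({sm.chrom: sm})
        pos = co_positions_from_events(events)
        anchors = pos[sm.chrom]
        assert len(anchors) == 2
        assert anchors[0] != anchors[1]
        icds = compute_icds(pos)
        assert icds.size == 1 and 200 <= icds[0] <= 600
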