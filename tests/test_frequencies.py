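"""Epsilon counting, exact intervals, Fisher tests and FDR control."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from apoeadmix import (
    EpsilonCounts,
    PopulationSpec,
    bh_adjust,
    clopper_pearson,
    count_epsilon,
    draw_diploid_apoe,
    fisher_pairwise,
    haplotype_to_sites,
)
from apoeadmix.frequencies import pairwise_frequency_tests
from apoeadmix.genotyping import GenotypeCall
from _oracles import bh_stepup, fisher_two_sided_enum


def _call(site, alleles):
    return GenotypeCall(site, tuple(sorted(alleles)) if alleles else None, 10, 40.0)


def _sample(g429358, g7412):
    return (_call("rs429358", g429358), _call("rs7412", g7412))


class TestCountEpsilon:
    def test_all_cc_at_rs7412_gives_zero_epsilon2(self):
        samples = [_sample(("T", "C"), ("C", "C")), _sample(("T", "T"), ("C", "C"))]
        counts = count_epsilon(samples, "WHG")
        assert counts.x_e2 == 0 and counts.n_e2 == 4

    def test_homozygous_e3_contributes_two_haplotypes(self):
        counts = count_epsilon([_sample(("T", "T"), ("C", "C"))])
        assert counts.x_e3 == 2 and counts.n_e3 == 2

    def test_double_het_resolved_as_e2_e4(self):
        counts = count_epsilon([_sample(("T", "C"), ("C", "T"))])
        assert counts.x_e3 == 0
        assert counts.x_e4 == 1 and counts.x_e2 == 1
        assert counts.n_ambiguous_dhet == 1

    def test_single_site_samples_extend_only_that_denominator(self):
        counts = count_epsilon([_sample(("C", "C"), None)])
        assert counts.n_e4 == 2 and counts.n_e2 == 0 and counts.n_e3 == 0

    def test_counts_sum_to_two_per_both_site_sample(self):
        spec = PopulationSpec("p", 0.15, 0.65, 0.20, 300)
        haps = draw_diploid_apoe(spec, 31)
        samples = [
            _sample(
                tuple(haplotype_to_sites(h)[0] for h in haps[i]),
                tuple(haplotype_to_sites(h)[1] for h in haps[i]),
            )
            for i in range(len(haps))
        ]
        counts = count_epsilon(samples)
        assert counts.x_e2 + counts.x_e3 + counts.x_e4 == 2 * len(samples)

    def test_phased_truth_recovered_without_double_hets(self):
        spec = PopulationSpec("p", 0.0, 0.7, 0.3, 200)  # no e2 -> no double hets
        haps = draw_diploid_apoe(spec, 37)
        samples = [
            _sample(
                tuple(haplotype_to_sites(h)[0] for h in haps[i]),
                tuple(haplotype_to_sites(h)[1] for h in haps[i]),
            )
            for i in range(len(haps))
        ]
        counts = count_epsilon(samples)
        assert counts.x_e3 == int((haps == "e3").sum())
        assert counts.n_ambiguous_dhet == 0

    def test_invariant_checked_on_construction(self):
        with pytest.raises(ValueError):
            EpsilonCounts("bad", x_e4=5, n_e4=4, x_e2=0, n_e2=4, x_e3=0, n_e3=4)


class TestClopperPearson:
    def test_zero_successes_has_zero_lower_bound(self):
        low, high = clopper_pearson(0, 10)
        assert low == 0.0 and high < 1.0

    def test_all_successes_has_unit_upper_bound(self):
        low, high = clopper_pearson(10, 10)
        assert high == 1.0 and low > 0.0

    def test_zero_successes_upper_bound_closed_form(self):
        _, high = clopper_pearson(0, 10, level=0.90)
        assert high == pytest.approx(1 - 0.05 ** (1 / 10), abs=1e-12)

    def test_undefined_for_empty_sample(self):
        with pytest.raises(ValueError):
            clopper_pearson(0, 0)

    def test_coverage_at_nominal_level(self, rng):
        # 90% interval contains the truth in >= ~90% of simulated replicates
        for f, n in ((0.1, 25), (0.5, 25), (0.3, 120)):
            x = rng.binomial(n, f, size=2000)
            lows = np.where(x == 0, 0.0, stats.beta.ppf(0.05, x, n - x + 1))
            highs = np.where(x == n, 1.0, stats.beta.ppf(0.95, x + 1, n - x))
            cover = np.mean((lows <= f) & (f <= highs))
            assert cover >= 0.90 - 3 * np.sqrt(0.1 * 0.9 / 2000)


def _ec(x, n, pop="A"):
    return EpsilonCounts(pop, x, n, 0, 0, 0, 0)


class TestFisherPairwise:
    def test_identical_tables_give_p_one(self):
        assert fisher_pairwise(_ec(3, 10), _ec(3, 10, "B"), "e4") == 1.0

    def test_zero_margin_gives_p_one(self):
        assert fisher_pairwise(_ec(0, 10), _ec(0, 6, "B"), "e4") == 1.0

    def test_small_table_matches_enumeration(self):
        p = fisher_pairwise(_ec(3, 4), _ec(1, 4, "B"), "e4")
        assert p == pytest.approx(fisher_two_sided_enum(3, 1, 1, 3), rel=1e-9)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.integers(0, 15), st.integers(0, 15), st.integers(0, 15), st.integers(0, 15))
    def test_agrees_with_exhaustive_enumeration(self, a, b, c, d):
        if a + b == 0 or c + d == 0:
            return
        p = fisher_pairwise(_ec(a, a + b), _ec(c, c + d, "B"), "e4")
        assert p == pytest.approx(fisher_two_sided_enum(a, b, c, d), rel=1e-7, abs=1e-12)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        adjusted, reject = bh_adjust([0.03])
        assert adjusted[0] == pytest.approx(0.03)
        assert reject[0]

    def test_equal_ps_stay_equal(self):
        adjusted, _ = bh_adjust([0.2] * 5)
        assert np.allclose(adjusted, 0.2)

    def test_example_matches_stepup_oracle(self):
        p = [0.01, 0.02, 0.03, 0.5]
        adjusted, _ = bh_adjust(p)
        assert np.allclose(adjusted, bh_stepup(p))

    def test_empty_family(self):
        adjusted, reject = bh_adjust([])
        assert adjusted.size == 0 and reject.size == 0

    def test_adjusted_never_below_raw(self, rng):
        p = rng.random(50)
        adjusted, _ = bh_adjust(p)
        assert (adjusted >= p - 1e-12).all()

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    def test_agrees_with_stepup_oracle(self, p):
        adjusted, _ = bh_adjust(p)
        assert np.allclose(adjusted, bh_stepup(p), atol=1e-12)


class TestPairwiseFamily:
    def test_all_pairs_and_alleles_pooled_into_one_family(self):
        pops = [
            EpsilonCounts("A", 10, 40, 2, 40, 25, 40),
            EpsilonCounts("B", 4, 40, 6, 40, 30, 40),
            EpsilonCounts("C", 20, 40, 1, 40, 18, 40),
        ]
        results = pairwise_frequency_tests(pops, q=0.05)
        assert len(results) == 3 * 3  # 3 pairs x 3 alleles
        raw = [r.p_raw for r in results]
        assert np.allclose([r.p_adjusted for r in results], bh_stepup(raw))
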