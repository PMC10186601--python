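"""FST variance components, Tajima's D, and the percentile backgrounds."""

import numpy as np
import pytest

from apoeadmix import fst_background, tajima_constants, tajimas_d, wc_fst_site, windowed_scan
from apoeadmix.scan import FstSite, PopSiteCounts
from _oracles import tajimas_d_direct, wc_fst_components


def _counts_from_genotypes(g):
    g = np.asarray(g)
    return PopSiteCounts(int(g.sum()), 2 * len(g), int((g == 1).sum()))


class TestWcFstSite:
    def test_fixed_difference_gives_theta_one(self):
        site = wc_fst_site(PopSiteCounts(20, 20, 0), PopSiteCounts(0, 20, 0))
        assert site.defined and site.theta == pytest.approx(1.0)

    def test_shared_monomorphism_undefined(self):
        site = wc_fst_site(PopSiteCounts(0, 20, 0), PopSiteCounts(0, 16, 0))
        assert not site.defined

    def test_too_few_chromosomes_undefined(self):
        site = wc_fst_site(PopSiteCounts(0, 0, 0), PopSiteCounts(5, 20, 3))
        assert not site.defined

    def test_matches_independent_component_coding(self, rng):
        for _ in range(300):
            n1, n2 = rng.integers(2, 30, size=2)
            g1 = rng.integers(0, 3, size=n1)
            g2 = rng.integers(0, 3, size=n2)
            site = wc_fst_site(_counts_from_genotypes(g1), _counts_from_genotypes(g2))
            a, b, c = wc_fst_components(
                n1, g1.sum() / (2 * n1), (g1 == 1).mean(),
                n2, g2.sum() / (2 * n2), (g2 == 1).mean(),
            )
            if a + b + c == 0:
                assert not site.defined
                continue
            assert site.a == pytest.approx(a, abs=1e-12)
            assert site.b == pytest.approx(b, abs=1e-12)
            assert site.c == pytest.approx(c, abs=1e-12)
            assert site.theta == pytest.approx(a / (a + b + c), abs=1e-12)

    def test_negative_estimates_retained(self, rng):
        # weak differentiation often yields small negative theta; it must
        # survive into the background distribution rather than be clamped
        thetas = []
        for _ in range(200):
            g1 = rng.binomial(2, 0.5, size=10)
            g2 = rng.binomial(2, 0.5, size=10)
            site = wc_fst_site(_counts_from_genotypes(g1), _counts_from_genotypes(g2))
            if site.defined:
                thetas.append(site.theta)
        assert min(thetas) < 0


class TestFstBackground:
    def _sites(self, values):
        return [FstSite(f"s{i}", 0, 0, 0, v, True) for i, v in enumerate(values)]

    def test_focal_maximum_exceeds_both_thresholds(self, rng):
        sites = self._sites(rng.random(100) * 0.1)
        sites.append(FstSite("focal", 0, 0, 0, 0.9, True))
        _, flags = fst_background(sites, focal_ids=["focal"])
        assert flags["focal"][95.0] and flags["focal"][97.5]

    def test_identical_values_never_strictly_above(self):
        sites = self._sites([0.1] * 50)
        _, flags = fst_background(sites, focal_ids=["s0"])
        assert not flags["s0"][95.0]

    def test_single_outlier_is_the_only_flagged_site(self, rng):
        values = list(rng.normal(0.02, 0.005, size=200))
        sites = self._sites(values)
        sites.append(FstSite("outlier", 0, 0, 0, 0.5, True))
        thresholds, flags = fst_background(
            sites, focal_ids=[s.site_id for s in sites]
        )
        flagged = [fid for fid, f in flags.items() if f[97.5]]
        assert "outlier" in flagged
        assert all(v <= thresholds[97.5] or fid == "outlier"
                   for fid, v in zip([s.site_id for s in sites],
                                     values + [0.5]) if fid not in flagged)

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError):
            fst_background(self._sites([0.1] * 5))

    def test_thresholds_invariant_under_permutation(self, rng):
        values = rng.random(80)
        t1, _ = fst_background(self._sites(values))
        t2, _ = fst_background(self._sites(values[::-1]))
        assert t1 == t2


class TestTajimasD:
    def test_constants_match_rational_arithmetic(self):
        k = tajima_constants(10)
        assert k["a1"] == pytest.approx(sum(1 / i for i in range(1, 10)), abs=1e-14)
        assert k["b1"] == pytest.approx(11 / 27)

    def test_zero_when_pi_equals_watterson(self):
        # n=4: 3 sites at count 2 and 8 at count 1 give pi = S/a1 exactly
        counts = [2] * 3 + [1] * 8
        window = tajimas_d(counts, 4)
        assert window.defined and window.D == pytest.approx(0.0, abs=1e-12)

    def test_monomorphic_window_undefined(self):
        window = tajimas_d([], 10)
        assert not window.defined and window.S == 0

    def test_fixed_sites_excluded_from_segregating(self):
        window = tajimas_d([0, 10, 3], 10)
        assert window.S == 1

    def test_hand_built_window_matches_direct_formula(self, rng):
        for _ in range(25):
            counts = rng.integers(1, 10, size=rng.integers(2, 30))
            assert tajimas_d(counts, 10).D == pytest.approx(
                tajimas_d_direct(counts, 10), abs=1e-10
            )

    def test_needs_four_chromosomes(self):
        with pytest.raises(ValueError):
            tajima_constants(3)


class TestWindowedScan:
    def test_boundary_site_belongs_to_next_window(self):
        positions = [0, 14_999, 15_000]
        windows, _ = windowed_scan(positions, [3, 3, 3], 10, focal_windows=(0,))
        assert windows[0].S == 2 and windows[1].S == 1

    def test_identical_windows_give_locus_at_median_without_flags(self):
        positions, counts = [], []
        for w in range(30):
            positions += [w * 15_000 + 10, w * 15_000 + 20]
            counts += [2, 5]
        windows, summary = windowed_scan(positions, counts, 10, focal_windows=(3, 4, 5))
        assert summary.locus_mean_d == pytest.approx(summary.d_percentiles[50.0])
        assert not summary.below_median and not summary.below_p5 and not summary.above_p95

    def test_locus_summary_averages_defined_focal_windows(self, rng):
        positions = list(rng.integers(0, 30 * 15_000, size=600))
        counts = list(rng.integers(1, 10, size=600))
        windows, summary = windowed_scan(positions, counts, 12, focal_windows=(10, 11, 12))
        focal = [w.D for w in windows if w.index in (10, 11, 12) and w.defined]
        assert summary.locus_mean_d == pytest.approx(np.mean(focal))

    def test_undefined_focal_windows_flagged(self):
        positions = [10, 20, 30]
        counts = [2, 3, 4]
        _, summary = windowed_scan(positions, counts, 10, focal_windows=(5, 6, 7))
        assert not summary.locus_defined
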