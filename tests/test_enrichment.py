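"""Enrichment statistics: coverage, shuffling, normal-tail test, positional
profile, size correlation, CTCF distances."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from triplextad.enrichment import (bp_coverage, ctcf_distance_test,
                                   enrichment_test, positional_preference_test,
                                   positional_profile, shuffle_intervals,
                                   shuffled_coverages, size_coverage_correlation,
                                   tad_enrichment)
from triplextad.intervals import contained_in_any


def df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestCoverage:
    def test_spec_example(self):
        sites = df([("c", 90, 110), ("c", 150, 160)])
        region = df([("c", 100, 200)])
        assert bp_coverage(sites, region) == 20

    def test_empty_sites(self):
        assert bp_coverage(df([]), df([("c", 0, 100)])) == 0

    def test_identity_overlap(self):
        assert bp_coverage(df([("c", 100, 200)]), df([("c", 100, 200)])) == 100

    def test_chromosome_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            bp_coverage(df([("chrA", 0, 10)]), df([("chrB", 0, 10)]))


class TestShuffle:
    sizes = {"c1": 10_000, "c2": 5_000}

    def test_length_multiset_preserved(self, rng):
        sites = df([("c1", 0, 10), ("c1", 50, 80), ("c2", 100, 125)])
        want = sorted([10, 30, 25])
        for shuf in shuffle_intervals(sites, self.sizes, 20, rng=rng):
            assert sorted((shuf["end"] - shuf["start"]).tolist()) == want

    def test_exact_shuffle_count(self, rng):
        sites = df([("c1", 0, 10)])
        covs = shuffled_coverages(sites, df([("c1", 0, 5_000)]), self.sizes, 1000, rng=rng)
        assert covs.shape == (1000,)

    def test_constrained_mode_respects_allowed_space(self, rng):
        sites = df([("c1", 0, 10)] * 20)
        allowed = df([("c1", 2_000, 3_000), ("c2", 0, 500)])
        excl = df([("c1", 2_400, 2_600)])
        for shuf in shuffle_intervals(sites, self.sizes, 10, allowed_regions=allowed,
                                      excluded_regions=excl, rng=rng):
            from triplextad.intervals import subtract_intervals
            space = subtract_intervals(allowed, excl)
            assert contained_in_any(shuf, space).all()

    def test_site_longer_than_any_region_raises(self, rng):
        sites = df([("c1", 0, 600)])
        allowed = df([("c1", 0, 500)])
        with pytest.raises(ValueError, match="longer than any"):
            next(shuffle_intervals(sites, self.sizes, 1, allowed_regions=allowed, rng=rng))

    def test_mean_coverage_matches_direct_monte_carlo(self):
        # one 10-bp site on a 1000-bp chromosome vs region [0, 500)
        sizes = {"c": 1000}
        region = df([("c", 0, 500)])
        site = df([("c", 0, 10)])
        covs = shuffled_coverages(site, region, sizes, 20_000, rng=5)
        # independent oracle: enumerate all 991 placements exactly
        overlaps = [min(500, s + 10) - min(500, s) for s in range(991)]
        exact_mean = np.mean(overlaps)
        assert abs(covs.mean() - exact_mean) / exact_mean < 0.02


class TestEnrichmentTest:
    def test_observed_at_null_mean(self, rng):
        exp = rng.normal(1000, 50, size=500)
        res = enrichment_test(float(exp.mean()), exp)
        assert res.z == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(0.5, abs=1e-12)

    def test_closed_form_normal_tail(self, rng):
        # fitted N(1000, 50), observed 1100 → z = 2, upper p ≈ 0.02275
        exp = rng.normal(1000, 50, size=200_00)
        obs = exp.mean() + 2 * exp.std(ddof=1)
        res = enrichment_test(obs, exp)
        assert res.z == pytest.approx(2.0, abs=1e-9)
        assert res.p_value == pytest.approx(0.02275, abs=1e-4)

    def test_sentinel_below_1e16(self, rng):
        exp = rng.normal(1000, 50, size=100)
        res = enrichment_test(float(exp.mean() + 20 * exp.std()), exp)
        assert res.p_sentinel == "< 1e-16"
        assert res.p_display == "< 1e-16"

    def test_degenerate_null_raises(self):
        with pytest.raises(ValueError, match="zero standard deviation"):
            enrichment_test(10, np.full(100, 5.0))

    def test_too_few_values_raises(self):
        with pytest.raises(ValueError, match="30"):
            enrichment_test(10, np.arange(10))

    def test_strong_planted_enrichment_is_significant(self, default_bundle):
        from triplextad.triplex import TriplexParams, search_triplexes
        b = default_bundle        # enrichment factor 3
        sites = search_triplexes(b.lncrnas, b.genome, TriplexParams(), b.gene_of)
        res = tad_enrichment(sites, b.tads, b.chrom_sizes, 200, rng=0)
        assert res.p_sentinel or res.p_value < 1e-6


class TestPositional:
    def test_bin_arithmetic(self):
        tads = df([("c", 0, 100)])
        sites = df([("c", 58, 62)])
        prof = positional_profile(sites, tads, n_bins=5)
        assert prof.relative_positions[0] == pytest.approx(0.60)
        assert prof.bin_counts.tolist() == [0, 0, 0, 1, 0]

    def test_all_midpoint_sites_in_middle_bin(self):
        tads = df([("c", 0, 1000), ("c", 2000, 3000)])
        sites = df([("c", 498, 502), ("c", 2498, 2502)])
        prof = positional_profile(sites, tads, n_bins=5)
        assert prof.bin_counts.tolist() == [0, 0, 2, 0, 0]

    def test_zero_in_tad_sites_raises(self):
        tads = df([("c", 0, 100)])
        with pytest.raises(ValueError, match="no observed"):
            positional_preference_test(df([("c", 500, 510)]), tads, df([("c", 50, 60)]))

    def test_uniform_sites_ks_calibration(self):
        # uniformly planted in-TAD sites vs uniform control: p > 0.05 mostly
        tads = df([("c", 0, 50_000), ("c", 60_000, 110_000)])
        sizes = {"c": 120_000}
        ok = 0
        n_runs = 50
        for seed in range(n_runs):
            r = np.random.default_rng(seed)
            gen = shuffle_intervals(df([("c", 0, 20)] * 150), sizes, 2,
                                    allowed_regions=tads, rng=r)
            obs, ctl = next(gen), next(gen)
            res = positional_preference_test(obs, tads, ctl)
            ok += res.ks_pvalue > 0.05
        assert ok >= int(0.9 * n_runs)


class TestSizeCorrelation:
    def test_hand_computed_four_tads(self):
        tads = df([("c", 0, 100), ("c", 200, 400), ("c", 500, 800), ("c", 900, 1300)])
        sites = df([("c", 0, 10), ("c", 200, 240), ("c", 500, 530), ("c", 900, 980)])
        r, table = size_coverage_correlation(sites, tads)
        sizes = np.array([100, 200, 300, 400])
        normcov = np.array([10, 40, 30, 80]) / sizes
        want, _ = stats.pearsonr(sizes, normcov)
        assert r == pytest.approx(want, abs=1e-12)
        assert len(table) == 4

    def test_constant_ratio_gives_zero(self):
        tads = df([("c", 0, 100), ("c", 200, 400), ("c", 500, 900)])
        sites = tads          # coverage == size → ratio constant
        r, _ = size_coverage_correlation(sites, tads)
        assert r == 0.0

    def test_constant_sizes_raise(self):
        tads = df([("c", 0, 100), ("c", 200, 300), ("c", 400, 500)])
        with pytest.raises(ValueError, match="constant"):
            size_coverage_correlation(df([("c", 0, 10)]), tads)

    def test_random_sites_show_no_correlation(self):
        # with n TADs the null sd of r is ≈ 1/sqrt(n-3); 400 TADs put the
        # |r| < 0.1 band at ≈ 2 sd, so ≥ 90 % of runs should fall inside it
        rng = np.random.default_rng(99)
        sizes = {"c": 8_000_000}
        lens = rng.integers(3_000, 9_000, size=800)
        starts = np.cumsum(lens + 1_000) - lens
        tads = df([("c", int(s), int(s + l)) for s, l in zip(starts, lens)])
        hits = 0
        n_runs = 50
        for seed in range(n_runs):
            shuf = next(shuffle_intervals(df([("c", 0, 25)] * 1_000), sizes, 1, rng=seed))
            r, _ = size_coverage_correlation(shuf, tads)
            hits += abs(r) < 0.1
        assert hits >= int(0.9 * n_runs)


class TestCTCF:
    def test_overlapping_site_distance_zero(self):
        sites = df([("c", 100, 120)])
        ctcf = df([("c", 110, 115)])
        out = ctcf_distance_test(df([("c", 100, 120)] * 4), ctcf, ctcf, n_bins=4)
        assert out["chi2"] == 0.0 and out["p_value"] == 1.0

    def test_identical_samples_chi2_zero(self, rng):
        sites = df([("c", int(s), int(s) + 10) for s in rng.integers(0, 10_000, 50)])
        ctcf = df([("c", int(s), int(s) + 10) for s in rng.integers(0, 10_000, 20)])
        out = ctcf_distance_test(sites, ctcf, ctcf)
        assert out["chi2"] == 0.0 and out["p_value"] == 1.0

    def test_empty_ctcf_raises(self):
        with pytest.raises(ValueError, match="nonempty"):
            ctcf_distance_test(df([("c", 0, 10)]), df([]), df([("c", 0, 10)]))

    def test_uniform_tfs_vs_boundary_ctcf_usually_not_different(self):
        # uniform TFSs: distances to mildly boundary-enriched CTCF vs to
        # uniformly re-placed CTCF are indistinguishable in most runs
        from triplextad.synthetic import SyntheticConfig, simulate
        hits = 0
        n_runs = 30
        for seed in range(n_runs):
            cfg = SyntheticConfig(seed=seed, n_chroms=2, chrom_length=300_000,
                                  n_tads=12, tad_length_range=(8_000, 14_000),
                                  n_lncrnas=10, n_genes=10)
            b = simulate(cfg)
            r = np.random.default_rng(seed + 500)
            tfs = next(shuffle_intervals(df([("chr1", 0, 25)] * 120),
                                         b.chrom_sizes, 1, rng=r))
            rand_ctcf = next(shuffle_intervals(b.ctcf_sites, b.chrom_sizes, 1, rng=r))
            out = ctcf_distance_test(tfs, b.ctcf_sites, rand_ctcf)
            hits += out["p_value"] > 0.1
        assert hits > n_runs / 2
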