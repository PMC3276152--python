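import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, hypergeom

import fragilemap as fm
from fragilemap.association import exact_upper_p

from conftest import probe_mid_frame, random_instance


def brute_force_nearest(sites: pd.DataFrame, features: pd.DataFrame) -> np.ndarray:
    """Exhaustive pairwise-minimum oracle for nearest-feature distances."""
    out = np.full(len(sites), np.inf)
    for i, s in enumerate(sites.itertuples(index=False)):
        for f in features.itertuples(index=False):
            if f.chrom == s.chrom:
                out[i] = min(out[i], abs(s.midpoint - f.midpoint))
    return out


def yates_oracle(x1, n1, x2, n2):
    """Textbook Yates-corrected chi-square for a 2x2 table."""
    a, b, c, d = x1, n1 - x1, x2, n2 - x2
    n = n1 + n2
    num = n * (max(abs(a * d - b * c) - 0.5 * n, 0.0)) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    return num / den


class TestNearestDistance:
    def test_coincident_midpoints(self):
        feats = pd.DataFrame({"chrom": ["chrI"], "midpoint": [100.0]})
        assert fm.nearest_feature_distance(("chrI", 100.0), feats) == 0.0

    def test_other_chromosomes_are_infinitely_far(self):
        feats = pd.DataFrame({"chrom": ["chrI", "chrII"], "midpoint": [5000.0, 100.0]})
        assert fm.nearest_feature_distance(("chrI", 100.0), feats) == 4900.0
        only_ii = feats[feats["chrom"] == "chrII"]
        assert math.isinf(fm.nearest_feature_distance(("chrI", 100.0), only_ii))

    def test_matches_exhaustive_pairwise_oracle(self):
        rng = np.random.default_rng(7)
        chroms = ["chrA", "chrB", "chrC"]
        sites = pd.DataFrame({
            "chrom": rng.choice(chroms, 100),
            "midpoint": rng.uniform(0, 1e6, 100),
        })
        feats = pd.DataFrame({
            "chrom": rng.choice(chroms[:2], 20),  # chrC featureless
            "midpoint": rng.uniform(0, 1e6, 20),
        })
        got = fm.nearest_feature_distances(
            sites["chrom"].to_numpy(), sites["midpoint"].to_numpy(), feats
        )
        assert np.array_equal(got, brute_force_nearest(sites, feats))


class TestCountWithin:
    def test_coincident_sites_all_counted(self):
        feats = pd.DataFrame({"chrom": ["chrI"] * 3, "midpoint": [10.0, 20.0, 30.0]})
        sites = pd.DataFrame({"chrom": ["chrI"] * 3, "midpoint": [10.0, 20.0, 30.0]})
        assert fm.count_within(sites, feats, 6000) == 3

    def test_cutoff_boundary_is_inclusive(self):
        feats = pd.DataFrame({"chrom": ["chrI"], "midpoint": [10_000.0]})
        sites = pd.DataFrame({"chrom": ["chrI"], "midpoint": [16_000.0]})
        assert fm.count_within(sites, feats, 6000) == 1
        assert fm.count_within(sites, feats, 5999) == 0

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(19)
        for _ in range(10):
            _, _, feats, sites, cutoff = random_instance(
                rng, n_probes=50, n_sites=20, n_feats=5, chrom_len=100_000
            )
            expected = int((brute_force_nearest(sites, feats) <= cutoff).sum())
            assert fm.count_within(sites, feats, cutoff) == expected

    def test_cutoff_monotonicity(self):
        rng = np.random.default_rng(23)
        _, _, feats, sites, _ = random_instance(
            rng, n_probes=50, n_sites=20, n_feats=5, chrom_len=100_000
        )
        counts = [fm.count_within(sites, feats, c) for c in (500, 1500, 6000, 50_000)]
        assert counts == sorted(counts)


class TestProportionTest:
    def test_identical_proportions_degenerate(self):
        res = fm.proportion_test(10, 100, 10, 100)
        assert res.chi2_statistic == 0.0
        assert res.p_value == 1.0

    def test_matches_textbook_yates_formula(self):
        for x1, n1, x2, n2 in [(25, 100, 10, 100), (228, 639, 25, 639),
                               (5, 20, 15, 30), (1, 10, 9, 10)]:
            res = fm.proportion_test(x1, n1, x2, n2)
            stat = yates_oracle(x1, n1, x2, n2)
            assert res.chi2_statistic == pytest.approx(stat, abs=1e-10)
            assert res.p_value == pytest.approx(chi2.sf(stat, 1), abs=1e-12)

    def test_reported_breakage_percentages_are_highly_significant(self):
        # 41.6% vs 11.7% of 639 sites near checked vs unchecked origins
        res = fm.proportion_test(266, 639, 75, 639)
        assert res.p_value < 1e-15

    def test_degenerate_pooled_tables(self):
        assert fm.proportion_test(0, 10, 0, 20).p_value == 1.0
        assert fm.proportion_test(10, 10, 20, 20).p_value == 1.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            fm.proportion_test(11, 10, 0, 10)


class TestRandomSimulationTest:
    def test_saturated_universe_gives_p_one(self):
        layout = fm.GenomeLayout((("chrA", 10_000),))
        probes = fm.make_probe_grid(layout, spacing=1000, probe_length=60,
                                    seed=0, flag_fraction=0.0)
        feats = fm.features_from_records(
            [("chrA", 5000.0, "unchecked_origin", "ori")], layout
        )
        sites = probe_mid_frame(probes.iloc[:4])
        res = fm.random_simulation_test(sites, feats, probes, cutoff_bp=10_000,
                                        n_sims=200, seed=0)
        assert res.observed_count == res.n_sites == 4
        assert np.all(res.null_counts == 4)
        assert res.p_upper == 1.0

    def test_empty_feature_set_gives_p_one(self):
        layout = fm.GenomeLayout((("chrA", 10_000),))
        probes = fm.make_probe_grid(layout, spacing=1000, probe_length=60,
                                    seed=0, flag_fraction=0.0)
        feats = fm.features_from_records([], layout)
        sites = probe_mid_frame(probes.iloc[:3])
        res = fm.random_simulation_test(sites, feats, probes, n_sims=50, seed=1)
        assert res.observed_count == 0
        assert np.all(res.null_counts == 0)
        assert res.p_upper == 1.0

    def test_more_sites_than_universe_rejected(self):
        layout = fm.GenomeLayout((("chrA", 10_000),))
        probes = fm.make_probe_grid(layout, spacing=1000, probe_length=60,
                                    seed=0, flag_fraction=0.0)
        feats = fm.features_from_records([("chrA", 5000.0, "other", "f")], layout)
        sites = pd.DataFrame({"chrom": ["chrA"] * 11,
                              "midpoint": np.linspace(0, 9000, 11)})
        with pytest.raises(ValueError, match="universe"):
            fm.random_simulation_test(sites, feats, probes, n_sims=10, seed=0)

    def test_p_upper_is_the_exact_tie_inclusive_fraction(self):
        rng = np.random.default_rng(3)
        _, probes, feats, sites, cutoff = random_instance(rng)
        res = fm.random_simulation_test(sites, feats, probes, cutoff_bp=cutoff,
                                        n_sims=500, seed=4)
        manual = np.count_nonzero(res.null_counts >= res.observed_count) / 500
        assert res.p_upper == manual

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(5)
        _, probes, feats, sites, cutoff = random_instance(rng)
        a = fm.random_simulation_test(sites, feats, probes, cutoff, 300, seed=9)
        b = fm.random_simulation_test(sites, feats, probes, cutoff, 300, seed=9)
        assert np.array_equal(a.null_counts, b.null_counts)
        assert a.p_upper == b.p_upper

    def test_flagged_probes_excluded_from_null(self):
        layout = fm.GenomeLayout((("chrA", 20_000),))
        probes = fm.make_probe_grid(layout, spacing=1000, probe_length=60,
                                    seed=0, flag_fraction=0.0)
        # flag every probe outside the feature neighborhood: nulls saturate
        probes = probes.copy()
        feats = fm.features_from_records([("chrA", 1000.0, "other", "f")], layout)
        mid = (probes["start"] + probes["end"]) / 2.0
        probes["flagged"] = (mid - 1000.0).abs() > 2000
        sites = probe_mid_frame(probes.loc[~probes["flagged"]].iloc[:2])
        res = fm.random_simulation_test(sites, feats, probes, cutoff_bp=2000,
                                        n_sims=100, seed=2)
        assert np.all(res.null_counts == 2)

    def test_invariant_to_coordinate_translation_and_relabeling(self):
        rng = np.random.default_rng(8)
        layout, probes, feats, sites, cutoff = random_instance(
            rng, n_probes=20, n_sites=5, n_feats=3, chrom_len=50_000
        )
        res = fm.random_simulation_test(sites, feats, probes, cutoff, 400, seed=6)
        shift = 7000.0
        big = fm.GenomeLayout((("chrZ", 200_000),))
        probes2 = probes.assign(chrom="chrZ", start=probes["start"] + int(shift),
                                end=probes["end"] + int(shift))
        feats2 = feats.assign(chrom="chrZ", midpoint=feats["midpoint"] + shift)
        sites2 = sites.assign(chrom="chrZ", midpoint=sites["midpoint"] + shift)
        res2 = fm.random_simulation_test(sites2, feats2, probes2, cutoff, 400, seed=6)
        assert res2.observed_count == res.observed_count
        assert np.array_equal(res2.null_counts, res.null_counts)
        assert res2.p_upper == res.p_upper


class TestExhaustiveNull:
    def test_all_probes_near_features_mass_at_maximum(self):
        layout = fm.GenomeLayout((("chrA", 4000),))
        probes = fm.make_probe_grid(layout, spacing=1000, probe_length=60,
                                    seed=0, flag_fraction=0.0)
        feats = fm.features_from_records([("chrA", 2000.0, "other", "f")], layout)
        pmf = fm.exhaustive_null(2, feats, probes, cutoff_bp=4000)
        assert pmf == {2: 1.0}

    def test_single_site_enumeration(self):
        layout = fm.GenomeLayout((("chrA", 10_000),))
        probes = fm.make_probe_grid(layout, spacing=1000, probe_length=60,
                                    seed=0, flag_fraction=0.0)
        # probes near: midpoints 2030 +/- 1200 -> probes at 1030, 2030, 3030
        feats = fm.features_from_records([("chrA", 2030.0, "other", "f")], layout)
        pmf = fm.exhaustive_null(1, feats, probes, cutoff_bp=1200)
        assert pmf == {0: 0.7, 1: 0.3}

    def test_matches_hypergeometric_closed_form(self):
        rng = np.random.default_rng(11)
        _, probes, feats, sites, cutoff = random_instance(
            rng, n_probes=12, n_sites=3, n_feats=2, chrom_len=12_000
        )
        from fragilemap.association import _near_mask

        k = int(_near_mask(probes, feats, cutoff).sum())
        pmf = fm.exhaustive_null(3, feats, probes, cutoff_bp=cutoff)
        for c, p in pmf.items():
            assert p == pytest.approx(hypergeom.pmf(c, 12, k, 3), abs=1e-12)

    def test_combinatorial_bound_enforced(self):
        layout = fm.GenomeLayout((("chrA", 100_000),))
        probes = fm.make_probe_grid(layout, spacing=100, probe_length=60,
                                    seed=0, flag_fraction=0.0)
        feats = fm.features_from_records([("chrA", 5000.0, "other", "f")], layout)
        with pytest.raises(ValueError, match="Monte Carlo"):
            fm.exhaustive_null(10, feats, probes, cutoff_bp=1000)

    def test_monte_carlo_agrees_with_enumeration(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            _, probes, feats, sites, cutoff = random_instance(rng)
            pmf = fm.exhaustive_null(len(sites), feats, probes, cutoff_bp=cutoff)
            obs = fm.count_within(sites, feats, cutoff)
            exact = exact_upper_p(pmf, obs)
            res = fm.random_simulation_test(sites, feats, probes, cutoff,
                                            n_sims=20_000, seed=int(rng.integers(2**31)))
            se = math.sqrt(exact * (1 - exact) / 20_000)
            assert abs(res.p_upper - exact) <= 3 * se + 1e-12
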