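"""ΔSNP filtering, thresholds, window statistic and region calling."""

import numpy as np
import pandas as pd
import pytest

from necromap import bsa

from oracles import (
    bf_delta,
    bf_filter,
    bf_quantile,
    bf_window_proportions,
)


def make_sites(rows):
    return pd.DataFrame(rows, columns=bsa.SITE_COLUMNS)


def site(chrom, pos, nr=100, na=100, hr=100, ha=100, ref="A", alt="T"):
    return {
        "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
        "necrotic_ref": nr, "necrotic_alt": na,
        "healthy_ref": hr, "healthy_alt": ha,
    }


class TestFilterSites:
    def test_greedy_spacing_keeps_first_then_next_far_enough(self):
        sites = make_sites([site("Chr1", 100), site("Chr1", 150), site("Chr1", 250)])
        kept = bsa.filter_sites(sites, min_depth=100, min_spacing_bp=100)
        assert kept["pos"].tolist() == [100, 250]

    def test_depth_required_in_each_pool(self):
        sites = make_sites([site("Chr1", 100, nr=100, na=50, hr=50, ha=49)])
        assert len(bsa.filter_sites(sites, min_depth=100)) == 0

    def test_empty_input_ok(self):
        assert len(bsa.filter_sites(make_sites([]))) == 0

    def test_indels_dropped_and_counted(self):
        sites = make_sites([site("Chr1", 100, ref="AT"), site("Chr1", 300)])
        kept, stats = bsa.filter_sites(sites, return_stats=True)
        assert kept["pos"].tolist() == [300]
        assert stats.n_non_snp == 1

    def test_unsorted_input_rejected(self):
        sites = make_sites([site("Chr1", 300), site("Chr1", 100)])
        with pytest.raises(ValueError, match="sorted"):
            bsa.filter_sites(sites)

    def test_idempotent(self, random_site_table):
        raw = random_site_table(seed=5)
        once = bsa.filter_sites(raw)
        twice = bsa.filter_sites(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_spacing_resets_across_chromosomes(self):
        sites = make_sites([site("Chr1", 100), site("Chr2", 120)])
        assert len(bsa.filter_sites(sites)) == 2


class TestAlleleFrequencies:
    def test_arithmetic(self):
        sites = make_sites([site("Chr1", 100, nr=50, na=150, hr=100, ha=100)])
        track = bsa.allele_frequencies(sites)
        assert track["af_necrotic"].iloc[0] == 0.75
        assert track["af_healthy"].iloc[0] == 0.50
        assert track["delta"].iloc[0] == 0.25

    def test_identical_counts_give_zero_delta(self):
        track = bsa.allele_frequencies(make_sites([site("Chr1", 1)]))
        assert track["delta"].iloc[0] == 0.0

    def test_opposite_fixation_attains_bound(self):
        sites = make_sites([site("Chr1", 1, nr=0, na=200, hr=200, ha=0)])
        assert bsa.allele_frequencies(sites)["delta"].iloc[0] == 1.0

    def test_zero_depth_is_a_contract_violation(self):
        sites = make_sites([site("Chr1", 1, nr=0, na=0)])
        with pytest.raises(ValueError, match="zero total depth"):
            bsa.allele_frequencies(sites)


class TestGenomeThresholds:
    def test_uniform_grid_quantile_closed_form(self):
        # 101 evenly spaced deltas on [-1, 1]: 0.95 quantile = 0.90
        track = pd.DataFrame({"chrom": "Chr1", "pos": np.arange(101), "delta": np.linspace(-1, 1, 101)})
        th = bsa.genome_thresholds(track)
        assert th.upper_95 == pytest.approx(0.90)
        assert th.lower_05 == pytest.approx(-0.90)

    def test_constant_deltas_collapse_all_thresholds(self):
        track = pd.DataFrame({"chrom": "Chr1", "pos": [1, 2, 3], "delta": [0.2, 0.2, 0.2]})
        th = bsa.genome_thresholds(track)
        assert th.lower_01 == th.lower_05 == th.upper_95 == th.upper_99 == pytest.approx(0.2)

    def test_symmetric_deltas_give_mirrored_thresholds(self):
        deltas = np.concatenate([np.linspace(-1, 1, 200)])
        track = pd.DataFrame({"chrom": "Chr1", "pos": np.arange(200), "delta": deltas})
        th = bsa.genome_thresholds(track)
        assert th.lower_05 == pytest.approx(-th.upper_95)
        assert th.lower_01 == pytest.approx(-th.upper_99)

    def test_fewer_than_two_sites_rejected(self):
        track = pd.DataFrame({"chrom": ["Chr1"], "pos": [1], "delta": [0.0]})
        with pytest.raises(ValueError):
            bsa.genome_thresholds(track)


class TestWindowProportions:
    @staticmethod
    def track_of(deltas, chrom="Chr1"):
        return pd.DataFrame(
            {"chrom": chrom, "pos": 1 + 200 * np.arange(len(deltas)), "delta": deltas}
        )

    def test_remainder_rule_250_snps(self):
        th = bsa.QuantileThresholds(-0.5, -0.4, 0.4, 0.5)
        windows = bsa.window_proportions(self.track_of(np.zeros(250)), th, 100)
        assert windows["n_snps"].tolist() == [100, 100, 50]

    def test_small_remainder_merged_into_previous(self):
        th = bsa.QuantileThresholds(-0.5, -0.4, 0.4, 0.5)
        windows = bsa.window_proportions(self.track_of(np.zeros(240)), th, 100)
        assert windows["n_snps"].tolist() == [100, 140]

    def test_all_equal_deltas_are_never_outliers(self):
        track = self.track_of(np.full(300, 0.3))
        th = bsa.genome_thresholds(track)
        windows = bsa.window_proportions(track, th, 100)
        assert (windows["prop_05_95"] == 0).all()
        assert (windows["prop_01_99"] == 0).all()

    def test_hand_set_twelve_snp_example_matches_per_snp_check(self):
        deltas = [-0.9, -0.2, 0.0, 0.1, 0.95, -0.5, 0.2, 0.85, -0.45, 0.0, 0.3, 0.99]
        th = bsa.QuantileThresholds(-0.6, -0.4, 0.8, 0.9)
        windows = bsa.window_proportions(self.track_of(deltas), th, window_snps=4)
        expect = []
        for s in range(0, 12, 4):
            chunk = deltas[s : s + 4]
            expect.append(sum(1 for d in chunk if d < -0.4 or d > 0.8) / 4)
        assert windows["prop_05_95"].tolist() == expect

    def test_windows_never_span_chromosomes(self):
        track = pd.concat(
            [self.track_of(np.zeros(150), "Chr1"), self.track_of(np.zeros(30), "Chr2")],
            ignore_index=True,
        )
        th = bsa.QuantileThresholds(-0.5, -0.4, 0.4, 0.5)
        windows = bsa.window_proportions(track, th, 100)
        assert windows[windows.chrom == "Chr1"]["n_snps"].tolist() == [100, 50]
        assert windows[windows.chrom == "Chr2"]["n_snps"].tolist() == [30]

    def test_tiny_window_size_rejected(self):
        th = bsa.QuantileThresholds(-0.5, -0.4, 0.4, 0.5)
        with pytest.raises(ValueError):
            bsa.window_proportions(self.track_of(np.zeros(10)), th, window_snps=1)


class TestCallRegions:
    @staticmethod
    def windows_of(props, chrom="Chr1"):
        n = len(props)
        return pd.DataFrame(
            {
                "chrom": chrom,
                "start_bp": 1 + 1000 * np.arange(n),
                "end_bp": 1000 * (1 + np.arange(n)),
                "n_snps": 100,
                "n_out_05_95": (np.asarray(props) * 100).astype(int),
                "prop_05_95": props,
                "n_out_01_99": 0,
                "prop_01_99": 0.0,
            }
        )

    def test_single_run_merged(self):
        regions = bsa.call_regions(self.windows_of([0, 0, 0.8, 0.9, 0]))
        assert len(regions) == 1
        assert regions["peak_proportion"].iloc[0] == 0.9
        assert regions["n_windows"].iloc[0] == 2

    def test_no_hot_windows_gives_empty_list(self):
        assert len(bsa.call_regions(self.windows_of([0.1, 0.2, 0.0]))) == 0

    def test_runs_on_different_chromosomes_never_merge(self):
        w = pd.concat(
            [self.windows_of([0.9], "Chr1"), self.windows_of([0.8], "Chr2")],
            ignore_index=True,
        )
        regions = bsa.call_regions(w)
        assert len(regions) == 2
        assert set(regions["chrom"]) == {"Chr1", "Chr2"}


class TestOracleEquivalence:
    """Full-pipeline agreement with an independent brute-force implementation."""

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_pipeline_matches_brute_force_exactly(self, seed, random_site_table):
        raw = random_site_table(seed=seed, n_sites=900)
        records = raw.to_dict("records")

        kept = bsa.filter_sites(raw)
        bf_kept = bf_filter(records)
        assert kept["pos"].tolist() == [r["pos"] for r in bf_kept]

        track = bsa.allele_frequencies(kept)
        assert track["delta"].tolist() == pytest.approx([bf_delta(r) for r in bf_kept], abs=0)

        th = bsa.genome_thresholds(track)
        deltas = [bf_delta(r) for r in bf_kept]
        assert th.lower_05 == pytest.approx(bf_quantile(deltas, 0.05), abs=1e-12)
        assert th.upper_99 == pytest.approx(bf_quantile(deltas, 0.99), abs=1e-12)

        windows = bsa.window_proportions(track, th, 100)
        bf = bf_window_proportions(bf_kept, th.lower_05, th.upper_95, 100)
        assert windows["n_snps"].tolist() == [w["n_snps"] for w in bf]
        assert windows["prop_05_95"].tolist() == [w["prop"] for w in bf]

    def test_snp_weighted_window_mean_equals_global_outlier_fraction(self, random_site_table):
        raw = random_site_table(seed=77, n_sites=1000)
        track = bsa.allele_frequencies(bsa.filter_sites(raw))
        th = bsa.genome_thresholds(track)
        windows = bsa.window_proportions(track, th, 100)
        lo, up = th.pair("05_95")
        global_outliers = int(((track["delta"] < lo) | (track["delta"] > up)).sum())
        # exact, in integer arithmetic: windows partition the SNPs
        assert int(windows["n_out_05_95"].sum()) == global_outliers
        assert int(windows["n_snps"].sum()) == len(track)
        # the quantile construction caps the strict-outlier fraction at 10%
        # up to interpolation granularity (one extra site per tail)
        assert global_outliers / len(track) <= 0.10 + 2 / len(track)

    def test_invariance_to_processing_by_chromosome(self, random_site_table):
        raw = random_site_table(seed=21)
        whole = bsa.filter_sites(raw)
        parts = [
            bsa.filter_sites(grp.reset_index(drop=True))
            for _, grp in raw.groupby("chrom", sort=False)
        ]
        recombined = pd.concat(parts, ignore_index=True)
        pd.testing.assert_frame_equal(whole, recombined)

        th = bsa.genome_thresholds(bsa.allele_frequencies(whole))
        w_whole = bsa.window_proportions(bsa.allele_frequencies(whole), th, 100)
        w_parts = pd.concat(
            [bsa.window_proportions(bsa.allele_frequencies(p), th, 100) for p in parts],
            ignore_index=True,
        )
        pd.testing.assert_frame_equal(w_whole, w_parts)
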