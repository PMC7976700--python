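import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gvhotspots.intervals import GenomicInterval, ValidationError
from gvhotspots.selection import (
    SelectionConfig,
    call_selection_hotspots,
    decile_groups,
    earmark_candidates,
    matched_null_pvalue,
    matched_null_pvalues,
    merge_balancing_regions,
    nucleotide_diversity,
    tile_genome_1kb,
    window_selection_stats,
)


def windows_df(n, width=1000, chrom="chr1"):
    starts = np.arange(n) * width
    return pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + width})


class TestWindowStats:
    def test_saturated_daf_and_zero_delta(self):
        sites = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": [100, 600, 1500],
                "daf_AFR": 1.0,
                "daf_EUR": 1.0,
            }
        )
        stats = window_selection_stats(sites, windows_df(2))
        assert stats.loc[0, "mean_daf"] == pytest.approx(1.0)
        assert stats.loc[0, "delta_daf"] == pytest.approx(0.0)
        assert stats.loc[0, "n_informative"] == 2

    def test_max_pair_delta_over_three_pops(self):
        sites = pd.DataFrame(
            {"chrom": "chr1", "pos": [10], "daf_AFR": 0.1, "daf_EUR": 0.9, "daf_EAS": 0.5}
        )
        stats = window_selection_stats(sites, windows_df(1))
        assert stats.loc[0, "delta_daf"] == pytest.approx(0.8)

    def test_empty_window_undefined_not_zero(self):
        sites = pd.DataFrame({"chrom": "chr1", "pos": [100], "daf_AFR": 0.5})
        stats = window_selection_stats(sites, windows_df(3))
        assert np.isnan(stats.loc[1, "mean_daf"])
        assert stats.loc[1, "n_informative"] == 0

    def test_matches_naive_loop_oracle(self):
        rng = np.random.default_rng(0)
        n_sites = 400
        sites = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": np.sort(rng.integers(0, 100_000, n_sites)),
                "daf_AFR": rng.random(n_sites),
                "daf_EUR": rng.random(n_sites),
                "nsl": np.where(rng.random(n_sites) < 0.5, rng.normal(0, 1, n_sites), np.nan),
                "phylop": rng.normal(0, 1, n_sites),
            }
        )
        wins = windows_df(100)
        stats = window_selection_stats(sites, wins)
        for i in rng.choice(100, 20, replace=False):
            w = wins.iloc[i]
            sub = sites[(sites["pos"] >= w["start"]) & (sites["pos"] < w["end"])]
            if len(sub) == 0:
                assert stats.loc[i, "n_informative"] == 0
                continue
            daf = sub[["daf_AFR", "daf_EUR"]].to_numpy()
            assert stats.loc[i, "mean_daf"] == pytest.approx(daf.mean(axis=1).mean())
            assert stats.loc[i, "delta_daf"] == pytest.approx(
                np.abs(daf[:, 0] - daf[:, 1]).mean()
            )
            assert stats.loc[i, "n_informative"] == len(sub)


class TestNucleotideDiversity:
    def test_empty_window_zero(self):
        counts = pd.DataFrame({"chrom": "chr1", "pos": [50], "n_alt": [2], "n_total": [4]})
        pi = nucleotide_diversity(counts, windows_df(2))
        assert pi[1] == 0.0

    def test_hand_example(self):
        counts = pd.DataFrame({"chrom": "chr1", "pos": [50], "n_alt": [2], "n_total": [4]})
        pi = nucleotide_diversity(counts, windows_df(1))
        assert pi[0] == pytest.approx(2 / 3 / 1000)

    def test_pairwise_difference_oracle(self):
        rng = np.random.default_rng(1)
        n_total = 12
        pos = np.sort(rng.choice(1000, 50, replace=False))
        n_alt = rng.integers(1, n_total, 50)
        counts = pd.DataFrame({"chrom": "chr1", "pos": pos, "n_alt": n_alt, "n_total": n_total})
        pi = nucleotide_diversity(counts, windows_df(1))
        # O(n^2) haplotype-pair oracle
        hap = np.zeros((n_total, 50), dtype=int)
        for j, na in enumerate(n_alt):
            hap[:na, j] = 1
        diffs = [
            (hap[i] != hap[j]).sum()
            for i in range(n_total)
            for j in range(i + 1, n_total)
        ]
        assert pi[0] == pytest.approx(np.mean(diffs) / 1000)

    def test_allele_label_swap_invariant(self):
        counts = pd.DataFrame(
            {"chrom": "chr1", "pos": [10, 20], "n_alt": [3, 7], "n_total": [10, 10]}
        )
        swapped = counts.assign(n_alt=counts["n_total"] - counts["n_alt"])
        assert nucleotide_diversity(counts, windows_df(1))[0] == pytest.approx(
            nucleotide_diversity(swapped, windows_df(1))[0]
        )

    def test_validation(self):
        bad = pd.DataFrame({"chrom": "chr1", "pos": [10], "n_alt": [5], "n_total": [4]})
        with pytest.raises(ValidationError):
            nucleotide_diversity(bad, windows_df(1))


class TestEarmark:
    def test_upper_tail_with_ties(self):
        v = np.concatenate([np.arange(95), [99, 99, 99, 99, 99.0]])
        mask = earmark_candidates(v, "upper", 0.05)
        assert mask.sum() == 5

    def test_lower_tail(self):
        v = np.arange(100.0)
        mask = earmark_candidates(v, "lower", 0.05)
        assert set(np.flatnonzero(mask)) == set(range(5))

    def test_constant_metric_warns_all(self):
        with pytest.warns(UserWarning):
            mask = earmark_candidates(np.ones(50), "upper", 0.05)
        assert mask.all()

    def test_all_nan_errors(self):
        with pytest.raises(ValidationError):
            earmark_candidates(np.full(30, np.nan), "upper")


class TestMatchedNull:
    def test_top_candidate_minimal_p(self):
        values = np.concatenate([np.arange(100.0), [1000.0]])
        deciles = decile_groups(np.zeros(101))
        p = matched_null_pvalue(values, deciles, 100, "upper", n_sims=10_000,
                                rng=np.random.default_rng(0))
        assert p == pytest.approx(1 / 10_001)

    def test_median_candidate_half(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=2001)
        deciles = decile_groups(np.zeros(2001))
        c = int(np.argsort(values)[1000])
        p = matched_null_pvalue(values, deciles, c, "upper", n_sims=10_000, rng=rng)
        assert 0.45 < p < 0.55

    def test_deterministic_under_seed(self):
        values = np.random.default_rng(2).normal(size=500)
        deciles = decile_groups(np.zeros(500))
        p1 = matched_null_pvalue(values, deciles, 3, "upper", 1000, np.random.default_rng(7))
        p2 = matched_null_pvalue(values, deciles, 3, "upper", 1000, np.random.default_rng(7))
        assert p1 == p2

    def test_bounds_invariant(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=300)
        deciles = decile_groups(rng.integers(0, 50, 300))
        ps = matched_null_pvalues(values, deciles, np.arange(300), "upper", 200, rng)
        assert (ps >= 1 / 201).all() and (ps <= 1.0).all()

    def test_uniform_under_exchangeability(self):
        # windows exchangeable within deciles -> p approximately uniform
        rng = np.random.default_rng(4)
        values = rng.normal(size=5000)
        deciles = decile_groups(rng.poisson(5, 5000))
        cand = rng.choice(5000, 500, replace=False)
        ps = matched_null_pvalues(values, deciles, cand, "upper", 1000, rng)
        stat, p = sps.kstest(ps, "uniform")
        assert p > 0.01


class TestDecileGroups:
    def test_ties_share_lower_decile(self):
        n = np.array([0, 0, 0, 0, 1, 2, 3, 4, 5, 6])
        dec = decile_groups(n)
        assert len(set(dec[:4])) == 1  # all zeros in the same (lowest) group

    def test_balanced_when_distinct(self):
        dec = decile_groups(np.arange(1000))
        counts = np.bincount(dec)
        assert (counts == 100).all()


class TestCallSelectionHotspots:
    def _stats_with_run(self, seed=0, run_start=500, run_len=10):
        rng = np.random.default_rng(seed)
        n = 2000
        wins = windows_df(n)
        n_inf = rng.poisson(5, n).clip(1)
        daf = rng.beta(1, 3, n)  # background
        daf[run_start : run_start + run_len] = rng.beta(200, 4, run_len)  # ~0.98
        wins["mean_daf"] = daf
        wins["delta_daf"] = np.nan
        wins["mean_abs_nsl"] = np.nan
        wins["phylop"] = np.nan
        wins["pi"] = np.nan
        wins["n_informative"] = n_inf
        return wins

    def test_planted_run_yields_merged_hotspot(self):
        stats = self._stats_with_run()
        calls = call_selection_hotspots(stats, "PosSel", SelectionConfig(seed=0))
        overlapping = [
            c for c in calls if c.region.start < 510_000 and c.region.end > 500_000
        ]
        assert len(overlapping) == 1
        covered = overlapping[0].region.length // 1000
        assert covered >= 8

    def test_insignificant_earmarks_excluded(self):
        stats = self._stats_with_run()
        calls = call_selection_hotspots(stats, "PosSel", SelectionConfig(seed=0))
        for c in calls:
            assert c.empirical_p < 0.05

    def test_bad_mode_rejected(self):
        with pytest.raises(ValidationError):
            call_selection_hotspots(self._stats_with_run(), "Sideways")


class TestBalancing:
    def test_overlapping_merged(self):
        out = merge_balancing_regions(
            [
                [GenomicInterval("chr1", 0, 1000)],
                [GenomicInterval("chr1", 500, 2000)],
            ]
        )
        assert len(out) == 1
        assert (out[0].region.start, out[0].region.end) == (0, 2000)
        assert out[0].mode == "BalSel"

    def test_disjoint_passed_through_sorted(self):
        out = merge_balancing_regions(
            [[GenomicInterval("chr1", 5000, 6000)], [GenomicInterval("chr1", 0, 1000)]]
        )
        assert [(h.region.start, h.region.end) for h in out] == [(0, 1000), (5000, 6000)]
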