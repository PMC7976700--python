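import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gvhotspots.enrichment import (
    FeatureTrack,
    breakpoint_recurrency,
    distance_profile,
    empirical_p,
    feature_level,
    fold_change,
    gene_cluster_cnvt_test,
    maf_matched_enrichment,
    monte_carlo_enrichment,
    shuffle_regions,
)
from gvhotspots.intervals import GenomicInterval, ValidationError


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def track(entries, mode="density", name="t"):
    return FeatureTrack(name=name, mode=mode, entries=pd.DataFrame(entries))


class TestFeatureLevel:
    def test_full_coverage_density_one(self):
        t = track({"chrom": ["chr1"], "start": [0], "end": [2000]})
        assert feature_level(iv(500, 1500), t) == pytest.approx(1.0)

    def test_intensity_bp_weighted(self):
        t = track(
            {"chrom": ["chr1"], "start": [100], "end": [200], "score": [5.0]},
            mode="intensity",
        )
        assert feature_level(iv(0, 1000), t) == pytest.approx(0.5)

    def test_no_overlap_zero(self):
        t = track({"chrom": ["chr1"], "start": [5000], "end": [6000]})
        assert feature_level(iv(0, 1000), t) == 0.0

    def test_intensity_without_scores_rejected(self):
        with pytest.raises(ValidationError):
            track({"chrom": ["chr1"], "start": [0], "end": [10]}, mode="intensity")


class TestFoldChange:
    def test_region_equals_baseline(self):
        t = track({"chrom": ["chr1"], "start": [100], "end": [300]})
        space = [iv(0, 10_000)]
        assert fold_change(space, t, space) == pytest.approx(1.0)

    def test_planted_triple_density(self):
        rng = np.random.default_rng(0)
        # uniform background plus a 3x block in [0, 10k) of a 1-Mb genome
        bg = rng.integers(0, 1_000_000, 20_000)
        extra = rng.integers(0, 10_000, 400)
        starts = np.sort(np.concatenate([bg, extra]))
        t = track({"chrom": "chr1", "start": starts, "end": starts + 10})
        fold = fold_change([iv(0, 10_000)], t, [iv(0, 1_000_000)])
        assert fold == pytest.approx(3.0, rel=0.10)

    def test_scale_invariance_of_intensity_fold(self):
        e = {"chrom": ["chr1"] * 3, "start": [0, 500, 900], "end": [100, 700, 1000],
             "score": [1.0, 2.0, 3.0]}
        t1 = track(e, mode="intensity")
        e2 = dict(e, score=[10.0, 20.0, 30.0])
        t2 = track(e2, mode="intensity")
        regions, base = [iv(0, 500)], [iv(0, 1000)]
        assert fold_change(regions, t1, base) == pytest.approx(fold_change(regions, t2, base))

    def test_zero_baseline_errors(self):
        t = track({"chrom": ["chr2"], "start": [0], "end": [10]})
        with pytest.raises(ValidationError):
            fold_change([iv(0, 100)], t, [iv(0, 1000)])


class TestShuffleRegions:
    def test_lengths_preserved_and_inside_space(self):
        space = [iv(0, 10_000), iv(20_000, 25_000)]
        regions = [iv(0, 700), iv(100, 1400), iv(5, 35)]
        out = shuffle_regions(regions, space, rng=0)
        assert sorted(r.length for r in out) == sorted(r.length for r in regions)
        for r in out:
            assert any(b.start <= r.start and r.end <= b.end for b in space)

    def test_deterministic_under_seed(self):
        space = [iv(0, 50_000)]
        regions = [iv(0, 1000)] * 5
        a = shuffle_regions(regions, space, rng=42)
        b = shuffle_regions(regions, space, rng=42)
        assert a == b

    def test_uniform_starts(self):
        space = [iv(0, 1099)]  # 1000 valid starts for a 100-bp region
        rng = np.random.default_rng(1)
        starts = [
            shuffle_regions([iv(0, 100)], space, rng=rng)[0].start for _ in range(10_000)
        ]
        counts, _ = np.histogram(starts, bins=10, range=(0, 1000))
        stat, p = sps.chisquare(counts)
        assert p > 0.01

    def test_region_longer_than_space_errors(self):
        with pytest.raises(ValidationError):
            shuffle_regions([iv(0, 5000)], [iv(0, 1000)], rng=0)


class TestEmpiricalP:
    def test_printed_precision_value(self):
        assert round(empirical_p(0, 10_000), 4) == 0.0001

    def test_bounds(self):
        assert empirical_p(10_000, 10_000) == 1.0
        assert empirical_p(4_999_999, 5_000_000) == pytest.approx(1.0, abs=1e-6)

    def test_validation(self):
        with pytest.raises(ValidationError):
            empirical_p(5, 4)
        with pytest.raises(ValidationError):
            empirical_p(0, 0)

    def test_never_zero_and_decreasing_in_n(self):
        ps = [empirical_p(0, n) for n in (10, 100, 1000, 10_000)]
        assert all(p > 0 for p in ps)
        assert ps == sorted(ps, reverse=True)


class TestMonteCarlo:
    def test_shuffle_invariant_measure_p_one(self):
        res = monte_carlo_enrichment(
            [iv(0, 1000), iv(5000, 5600)],
            measure=lambda rs: sum(r.length for r in rs),
            space=[iv(0, 100_000)],
            n_sims=50,
            seed=0,
        )
        assert res.empirical_p == 1.0

    def test_enrich_deplete_counting_identity(self):
        rng = np.random.default_rng(2)
        anchors = np.sort(rng.integers(0, 100_000, 500))

        def density(rs):
            return sum(
                int(np.searchsorted(anchors, r.end) - np.searchsorted(anchors, r.start))
                for r in rs
            )

        kw = dict(measure=density, space=[iv(0, 100_000)], n_sims=200, seed=5)
        pe = monte_carlo_enrichment([iv(40_000, 42_000)], direction="enrich", **kw).empirical_p
        pd_ = monte_carlo_enrichment([iv(40_000, 42_000)], direction="deplete", **kw).empirical_p
        assert pe + pd_ >= 1 + 1 / 201 - 1e-12

    def test_planted_excess_small_p(self):
        rng = np.random.default_rng(3)
        anchors = np.sort(
            np.concatenate([rng.integers(0, 100_000, 300), rng.integers(40_000, 42_000, 200)])
        )

        def density(rs):
            return sum(
                int(np.searchsorted(anchors, r.end) - np.searchsorted(anchors, r.start))
                for r in rs
            )

        res = monte_carlo_enrichment(
            [iv(40_000, 42_000)], density, [iv(0, 100_000)], n_sims=200, seed=1
        )
        assert res.empirical_p == pytest.approx(1 / 201)
        assert res.fold > 5


class TestDistanceProfile:
    def test_spike_at_zero_when_features_at_anchors(self):
        anchors = np.array([10_000, 20_000, 30_000])
        entries = pd.DataFrame(
            {"chrom": "chr1", "start": anchors, "end": anchors + 10}
        )
        prof = distance_profile(anchors, track(entries.to_dict("list")), "chr1", 1000, 50)
        peak = prof.loc[prof["value"].idxmax(), "offset"]
        assert peak == 0

    def test_planted_decay_recovered(self):
        rng = np.random.default_rng(4)
        anchors = np.sort(rng.integers(50_000, 950_000, 40))
        offsets = (rng.exponential(800, 4000)).astype(int)
        signs = rng.choice([-1, 1], 4000)
        pos = np.clip(anchors[rng.integers(0, len(anchors), 4000)] + signs * offsets, 0, 10**6)
        entries = {"chrom": ["chr1"] * len(pos), "start": list(pos), "end": list(pos + 5)}
        prof = distance_profile(anchors, track(entries), "chr1", 4000, 200)
        dist = np.abs(prof["offset"] + 100)  # bin centres
        rho = sps.spearmanr(dist, prof["value"]).statistic
        assert rho < -0.9


class TestGeneClusterTest:
    def test_hand_computed_chi_square(self):
        genes = pd.DataFrame(
            [("G1", "chr1", 0, 10_000)], columns=["gene", "chrom", "start", "end"]
        )
        clusters = [iv(2000, 3000)]
        bps = pd.DataFrame({"chrom": "chr1", "pos": np.linspace(2100, 2900, 20).astype(int)})
        out = gene_cluster_cnvt_test(genes, clusters, bps)
        row = out.iloc[0]
        assert row["expected"] == pytest.approx(2.0)
        assert row["chi2"] == pytest.approx(180.0)
        assert row["p"] < 1e-40
        assert row["direction"] == "enriched"

    def test_expected_equals_observed_p_one(self):
        genes = pd.DataFrame(
            [("G1", "chr1", 0, 10_000)], columns=["gene", "chrom", "start", "end"]
        )
        clusters = [iv(0, 5000)]
        bps = pd.DataFrame({"chrom": "chr1", "pos": [1000, 2000, 6000, 7000]})
        out = gene_cluster_cnvt_test(genes, clusters, bps)
        assert out.iloc[0]["chi2"] == pytest.approx(0.0)
        assert out.iloc[0]["p"] == pytest.approx(1.0)

    def test_null_calibration_uniform_breakpoints(self):
        rng = np.random.default_rng(6)
        genes = pd.DataFrame(
            [("G1", "chr1", 0, 50_000)], columns=["gene", "chrom", "start", "end"]
        )
        clusters = [iv(10_000, 20_000)]
        n_ok = 0
        for _ in range(100):
            bps = pd.DataFrame({"chrom": "chr1", "pos": rng.integers(0, 50_000, 60)})
            out = gene_cluster_cnvt_test(genes, clusters, bps)
            if out.iloc[0]["p"] > 0.05:
                n_ok += 1
        assert n_ok >= 90

    def test_gene_without_breakpoints_skipped(self):
        genes = pd.DataFrame(
            [("G1", "chr1", 0, 10_000)], columns=["gene", "chrom", "start", "end"]
        )
        out = gene_cluster_cnvt_test(genes, [iv(0, 1000)], pd.DataFrame({"chrom": [], "pos": []}))
        assert len(out) == 0


class TestRecurrency:
    def test_all_unique_zero(self):
        bps = pd.DataFrame(
            {"chrom": "chr1", "pos": [100, 5100, 9100], "sample": ["a", "b", "c"]}
        )
        assert breakpoint_recurrency(bps, [iv(0, 10_000)]) == 0.0

    def test_shared_site_full(self):
        bps = pd.DataFrame(
            {"chrom": "chr1", "pos": [500] * 5, "sample": list("abcde")}
        )
        assert breakpoint_recurrency(bps, [iv(0, 10_000)]) == 1.0

    def test_region_restriction(self):
        bps = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": [500, 510, 90_000],
                "sample": ["a", "b", "c"],
            }
        )
        assert breakpoint_recurrency(bps, [iv(0, 1000)]) == 1.0
        assert breakpoint_recurrency(bps, [iv(80_000, 95_000)]) == 0.0


class TestMafMatched:
    def test_planted_enrichment_detected(self):
        rng = np.random.default_rng(7)
        n_win = 400
        windows = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(n_win) * 1000,
                "end": (np.arange(n_win) + 1) * 1000,
                "mean_maf": rng.uniform(0.05, 0.4, n_win),
            }
        )
        snp_pos = np.sort(rng.integers(0, n_win * 1000, 8000))
        snps = pd.DataFrame({"chrom": "chr1", "pos": snp_pos})
        base = rng.random(8000) < 0.05
        boost = base | ((snp_pos < 10_000) & (rng.random(8000) < 0.5))
        gwas = snps[boost]
        res = maf_matched_enrichment(
            [iv(0, 10_000)], gwas, windows, snp_positions=snps, n_sims=500, seed=0
        )
        assert res.empirical_p < 0.01
        no_signal = maf_matched_enrichment(
            [iv(200_000, 210_000)], gwas, windows, snp_positions=snps, n_sims=500, seed=0
        )
        assert no_signal.empirical_p > 0.05
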