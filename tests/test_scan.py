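import numpy as np
import pandas as pd
import pytest

from gvhotspots.catalog import VariantCatalog
from gvhotspots.intervals import GenomicInterval, ValidationError, ZonePartition
from gvhotspots.scan import (
    ScanConfig,
    build_weights,
    detect_hotspots,
    recruit_top_windows,
    scan_chromosome,
    weighted_density,
)


class TestWeights:
    def test_endpoints_and_sum(self):
        w = build_weights(100).w
        assert w[0] == 0.5 and w[-1] == 0.5
        assert w[49] == 1.0 and w[50] == 1.0
        assert w.sum() == pytest.approx(75.0)

    def test_symmetry_and_equal_increments(self):
        w = build_weights(100).w
        assert np.allclose(w, w[::-1])
        diffs = np.diff(w[:50])
        assert np.allclose(diffs, 0.5 / 49)

    def test_odd_n_rejected(self):
        with pytest.raises(ValidationError):
            build_weights(99)


class TestWeightedDensity:
    def test_uniform_counts_equal_mean(self):
        scheme = build_weights(100)
        assert weighted_density(np.full(100, 3), scheme) == pytest.approx(3.0)

    def test_central_and_marginal_steps(self):
        scheme = build_weights(100)
        counts = np.zeros(100)
        counts[49] = counts[50] = 3
        assert weighted_density(counts, scheme) == pytest.approx(6 / 75)
        counts = np.zeros(100)
        counts[0] = 3
        assert weighted_density(counts, scheme) == pytest.approx(1.5 / 75)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            weighted_density(np.zeros(50), build_weights(100))


def brute_force_scan(anchors, extent, width=1000, step=10):
    """Naive per-window enumeration oracle."""
    scheme = build_weights(width // step)
    anchors = np.asarray(sorted(anchors))
    d, raw = [], []
    for start in range(0, extent - width + 1, step):
        counts = np.zeros(width // step)
        for a in anchors:
            if start <= a < start + width:
                counts[(a - start) // step] += 1
        d.append(weighted_density(counts, scheme))
        raw.append(int(counts.sum()))
    return np.array(d), np.array(raw)


class TestScanChromosome:
    def test_empty_catalog_zero(self):
        scan = scan_chromosome(np.array([], dtype=int), "chr1", 50_000)
        assert scan.n_windows == (50_000 - 1000) // 10 + 1
        assert not scan.d.any()

    def test_single_interior_anchor_hits_100_windows(self):
        scan = scan_chromosome(np.array([25_000]), "chr1", 50_000)
        assert int((scan.raw == 1).sum()) == 100
        assert scan.raw.sum() == 100

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        anchors = np.sort(rng.integers(0, 50_000, 200))
        scan = scan_chromosome(anchors, "chr1", 50_000)
        d, raw = brute_force_scan(anchors, 50_000)
        assert np.allclose(scan.d, d)
        assert np.array_equal(scan.raw, raw)


class TestRecruitment:
    def test_single_window_at_budget(self):
        # top window alone covers 5 of 100 entries at the 5% target
        part1_entries = [np.arange(5), np.arange(5, 11)]
        rec1, rec2, d_min = recruit_top_windows(
            np.array([2.0, 1.5]), part1_entries, np.array([]), total_entries=100
        )
        assert rec1 == [0] and d_min == 2.0

    def test_next_window_exceeding_budget_not_recruited(self):
        part1_entries = [np.arange(5), np.arange(5, 7)]  # adding second -> 7%
        rec1, _, _ = recruit_top_windows(
            np.array([2.0, 1.5]), part1_entries, np.array([]), total_entries=100
        )
        assert rec1 == [0]

    def test_part2_ties_at_dmin_recruited(self):
        part1_entries = [np.arange(5)]
        rec1, rec2, d_min = recruit_top_windows(
            np.array([2.0]), part1_entries, np.array([2.0, 1.99]), total_entries=100
        )
        assert rec2 == [0]  # exactly d_min recruited, below excluded

    def test_zero_entries_warns_empty(self):
        with pytest.warns(UserWarning):
            rec1, rec2, d_min = recruit_top_windows(
                np.array([1.0]), [np.arange(3)], np.array([]), total_entries=0
            )
        assert rec1 == [] and d_min is None

    def test_tied_boundary_group_all_or_none(self):
        # two tied windows whose joint inclusion would exceed the budget
        part1_entries = [np.arange(4), np.arange(4, 8), np.arange(8, 12)]
        rec1, _, _ = recruit_top_windows(
            np.array([2.0, 1.0, 1.0]), part1_entries, np.array([]), total_entries=100
        )
        assert rec1 == [0]


def toy_zones(n_windows=1, window=50_000, label="Genic"):
    wins = [
        (GenomicInterval("chr1", i * window, (i + 1) * window), label)
        for i in range(n_windows)
    ]
    return ZonePartition(windows=wins)


def snp_catalog(positions):
    df = pd.DataFrame(
        [("chr1", int(p), int(p) + 1, "SNP", None, None, None) for p in positions],
        columns=VariantCatalog.COLUMNS,
    )
    return VariantCatalog(df)


def brute_force_detect(positions, zones, config=None):
    """Exhaustive single-zone-type hotspot caller for toy chromosomes."""
    config = config or ScanConfig()
    positions = np.sort(np.asarray(positions))
    extent = zones.chrom_extent("chr1")
    d, raw = brute_force_scan(positions, extent, config.width, config.step)
    union = zones.zone_union("Genic")
    n_win = len(d)
    part1 = np.zeros(n_win, dtype=bool)
    for iv in union:
        for k in range(n_win):
            s = k * config.step
            part1[k] |= iv.start <= s and s + config.width <= iv.end
    in_zone = sum(
        1 for p in positions if any(iv.start <= p < iv.end for iv in union)
    )
    budget = config.target_fraction * in_zone
    order = np.argsort(-d, kind="stable")
    covered = set()
    recruited = []
    i = 0
    order = [k for k in order if part1[k]]
    while i < len(order):
        j = i
        while j < len(order) and d[order[j]] == d[order[i]]:
            j += 1
        group = order[i:j]
        new = set()
        for k in group:
            s = k * config.step
            new |= {int(p) for p in positions if s <= p < s + config.width}
        if len(covered | new) > budget:
            break
        covered |= new
        recruited.extend(group)
        i = j
    regions = []
    for k in sorted(recruited):
        s, e = k * config.step, k * config.step + config.width
        if regions and s <= regions[-1][1]:
            regions[-1][1] = max(regions[-1][1], e)
        else:
            regions.append([s, e])
    return [tuple(r) for r in regions]


class TestDetectHotspots:
    def test_matches_exhaustive_oracle_on_toy_chromosome(self):
        rng = np.random.default_rng(42)
        positions = np.concatenate(
            [rng.integers(0, 50_000, 300), rng.integers(20_000, 22_000, 120)]
        )
        zones = toy_zones()
        calls = detect_hotspots(snp_catalog(positions), zones, "SNP")
        expected = brute_force_detect(positions, zones)
        got = [(c.region.start, c.region.end) for c in calls]
        assert got == expected

    def test_calls_disjoint_and_planted_block_found(self):
        rng = np.random.default_rng(1)
        positions = np.concatenate(
            [rng.integers(0, 100_000, 3000), rng.integers(40_000, 45_000, 400)]
        )
        zones = toy_zones(n_windows=2)
        calls = detect_hotspots(snp_catalog(positions), zones, "SNP")
        regions = sorted((c.region.start, c.region.end) for c in calls)
        for (s1, e1), (s2, e2) in zip(regions, regions[1:]):
            assert e1 < s2  # pairwise disjoint (book-ended merged away)
        top = max(calls, key=lambda c: c.max_d).region
        assert top.start < 45_000 and top.end > 40_000

    def test_zone_crossing_window_counted_once(self):
        # dense block straddling a Genic/Proximal boundary: windows crossing
        # the boundary are Part II for both labels but must yield one call
        rng = np.random.default_rng(2)
        wins = [
            (GenomicInterval("chr1", 0, 50_000), "Genic"),
            (GenomicInterval("chr1", 50_000, 100_000), "Proximal"),
        ]
        zones = ZonePartition(windows=wins)
        positions = np.concatenate(
            [rng.integers(0, 100_000, 3000), rng.integers(49_000, 51_000, 80)]
        )
        calls = detect_hotspots(snp_catalog(positions), zones, "SNP")
        crossing = [c for c in calls if c.region.start < 50_000 < c.region.end]
        assert len(crossing) == 1
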