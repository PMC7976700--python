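"""Feature quantitation, Monte Carlo enrichment and gene-level tests.

Feature levels are measured as Density (covered bp / region bp) for
interval features or Intensity (bp-weighted score / region bp) for
scored features.  Enrichment significance uses size-matched shuffles of
the target regions within the analyzed space and the empirical
p = (r+1)/(n+1); GWAS-SNP enrichment additionally matches the null on
windows' average minor-allele frequency to absorb the allele-frequency
dependence of GWAS discovery.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .intervals import GenomicInterval, ValidationError, merge_intervals


@dataclass
class FeatureTrack:
    """Interval (density) or scored-interval (intensity) feature."""

    name: str
    mode: str  # "density" | "intensity"
    entries: pd.DataFrame  # chrom, start, end [, score]

    def __post_init__(self) -> None:
        if self.mode not in ("density", "intensity"):
            raise ValidationError(f"mode must be density/intensity, got {self.mode!r}")
        if self.mode == "intensity":
            if "score" not in self.entries.columns or self.entries["score"].isna().any():
                raise ValidationError("intensity track requires a score on every entry")


@dataclass
class EnrichmentResult:
    observed: float
    null_mean: float
    fold: float
    empirical_p: float
    n_sims: int
    seed: int
    direction: str = "enrich"


def _clipped_overlap(
    regions: Sequence[GenomicInterval], entries: pd.DataFrame
) -> tuple[float, float]:
    """(total clipped bp, total clipped bp x score) over all regions."""
    bp_total = 0.0
    wsum_total = 0.0
    has_score = "score" in entries.columns
    for chrom, sub in entries.groupby("chrom", sort=False):
        rs = [r for r in regions if r.chrom == chrom]
        if not rs:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        scores = sub["score"].to_numpy(dtype=float) if has_score else None
        for r in rs:
            clip = np.minimum(ends, r.end) - np.maximum(starts, r.start)
            clip = np.clip(clip, 0, None)
            bp_total += clip.sum()
            if scores is not None:
                wsum_total += float((clip * scores).sum())
    return bp_total, wsum_total


def feature_level(region: GenomicInterval, track: FeatureTrack) -> float:
    """Density or Intensity of a feature in one region."""
    return aggregate_level([region], track)


def aggregate_level(regions: Sequence[GenomicInterval], track: FeatureTrack) -> float:
    """Feature level pooled over a region set (overlap-clipped)."""
    total_bp = sum(r.length for r in regions)
    if total_bp == 0:
        raise ValidationError("region set has zero width")
    bp, wsum = _clipped_overlap(regions, track.entries)
    if track.mode == "density":
        return bp / total_bp
    return wsum / total_bp


def fold_change(
    regions: Sequence[GenomicInterval],
    track: FeatureTrack,
    baseline_space: Sequence[GenomicInterval],
) -> float:
    """Feature level in ``regions`` relative to the baseline space."""
    base = aggregate_level(baseline_space, track)
    if base == 0:
        raise ValidationError("undefined fold: baseline level is zero")
    return aggregate_level(regions, track) / base


# ---------------------------------------------------------------------------
# shuffling


class RegionShuffler:
    """Uniform placement of size-matched surrogate regions in a space.

    The analyzed space is a set of disjoint blocks; a surrogate of
    length L lands uniformly over every valid start among blocks of
    length >= L.  Shuffled regions may overlap one another.
    """

    def __init__(self, space: Sequence[GenomicInterval]):
        self.blocks = merge_intervals(space)
        self.b_chrom = [b.chrom for b in self.blocks]
        self.b_start = np.array([b.start for b in self.blocks], dtype=np.int64)
        self.b_len = np.array([b.length for b in self.blocks], dtype=np.int64)

    def sample(
        self, lengths: Sequence[int], rng: np.random.Generator
    ) -> list[GenomicInterval]:
        out = []
        for L in lengths:
            valid = self.b_len - L + 1
            valid = np.clip(valid, 0, None)
            total = valid.sum()
            if total <= 0:
                raise ValidationError(
                    f"region of length {L} exceeds every space block"
                )
            u = rng.integers(total)
            b = int(np.searchsorted(np.cumsum(valid), u, side="right"))
            offset = u - (np.cumsum(valid)[b - 1] if b else 0)
            s = int(self.b_start[b] + offset)
            out.append(GenomicInterval(self.b_chrom[b], s, s + L))
        return out


def shuffle_regions(
    regions: Sequence[GenomicInterval],
    space: Sequence[GenomicInterval],
    rng: np.random.Generator | int | None = None,
) -> list[GenomicInterval]:
    """One round of number- and size-matched random placement."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return RegionShuffler(space).sample([r.length for r in regions], rng)


def empirical_p(r: int, n: int) -> float:
    """Monte Carlo empirical p-value (r+1)/(n+1); never zero."""
    if n < 1:
        raise ValidationError("need at least one simulation round")
    if not (0 <= r <= n):
        raise ValidationError(f"r={r} outside [0, {n}]")
    return (r + 1) / (n + 1)


def monte_carlo_enrichment(
    regions: Sequence[GenomicInterval],
    measure: Callable[[Sequence[GenomicInterval]], float],
    space: Sequence[GenomicInterval],
    n_sims: int = 1000,
    direction: str = "enrich",
    seed: int = 0,
) -> EnrichmentResult:
    """Enrichment/depletion of a measurement against shuffled surrogates.

    r counts simulations with a measurement >= the observed level
    (enrichment) or <= it (depletion).  The genome-scale default of
    5,000,000 rounds is impractical for most uses; pass what the
    analysis needs.
    """
    if direction not in ("enrich", "deplete"):
        raise ValidationError("direction must be enrich or deplete")
    rng = np.random.default_rng(seed)
    shuffler = RegionShuffler(space)
    lengths = [r.length for r in regions]
    observed = float(measure(regions))
    null = np.empty(n_sims)
    for i in range(n_sims):
        null[i] = measure(shuffler.sample(lengths, rng))
    r = int((null >= observed).sum()) if direction == "enrich" else int((null <= observed).sum())
    null_mean = float(null.mean())
    fold = observed / null_mean if null_mean else np.inf
    return EnrichmentResult(
        observed=observed,
        null_mean=null_mean,
        fold=fold,
        empirical_p=empirical_p(r, n_sims),
        n_sims=n_sims,
        seed=seed,
        direction=direction,
    )


# ---------------------------------------------------------------------------
# MAF-matched GWAS enrichment


def maf_matched_enrichment(
    hotspots: Sequence[GenomicInterval],
    gwas_positions: pd.DataFrame,
    windows: pd.DataFrame,
    snp_positions: pd.DataFrame | None = None,
    n_sims: int = 1000,
    seed: int = 0,
    statistic: str = "snp_fraction",
    n_groups: int = 10,
) -> EnrichmentResult:
    """GWAS-SNP enrichment with the null matched on window mean MAF.

    Windows (columns ``chrom, start, end, mean_maf``) are split into ten
    equal groups by average MAF; each hotspot is assigned the group of
    its mean MAF, and every simulation draws one window per hotspot from
    that group.  The default statistic is the GWAS fraction of SNPs
    (ascertainment rate), which isolates the allele-frequency channel;
    ``statistic="bp_density"`` uses GWAS SNPs per bp instead.

    ``gwas_positions`` and ``snp_positions``: columns ``chrom, pos``.
    """
    if statistic not in ("snp_fraction", "bp_density"):
        raise ValidationError(f"unknown statistic {statistic!r}")
    if statistic == "snp_fraction" and snp_positions is None:
        raise ValidationError("snp_fraction statistic needs snp_positions")
    rng = np.random.default_rng(seed)

    win = windows.dropna(subset=["mean_maf"]).reset_index(drop=True)
    if len(win) < n_groups:
        raise ValidationError("need at least one window per MAF group")
    groups = pd.qcut(win["mean_maf"].rank(method="first"), n_groups, labels=False).to_numpy()

    pos_by_chrom = {
        chrom: np.sort(sub["pos"].to_numpy())
        for chrom, sub in gwas_positions.groupby("chrom", sort=False)
    }
    snp_by_chrom = (
        {
            chrom: np.sort(sub["pos"].to_numpy())
            for chrom, sub in snp_positions.groupby("chrom", sort=False)
        }
        if snp_positions is not None
        else {}
    )

    def counts_in(by_chrom: dict, regions: Sequence[GenomicInterval]) -> int:
        total = 0
        for r in regions:
            pos = by_chrom.get(r.chrom)
            if pos is not None:
                lo, hi = np.searchsorted(pos, [r.start, r.end])
                total += int(hi - lo)
        return total

    def per_window_counts(by_chrom: dict) -> np.ndarray:
        out = np.zeros(len(win), dtype=float)
        for chrom in win["chrom"].unique():
            sel = (win["chrom"] == chrom).to_numpy()
            pos = by_chrom.get(chrom)
            if pos is None:
                continue
            lo = np.searchsorted(pos, win.loc[sel, "start"].to_numpy())
            hi = np.searchsorted(pos, win.loc[sel, "end"].to_numpy())
            out[sel] = hi - lo
        return out

    gwas_per_win = per_window_counts(pos_by_chrom)
    if statistic == "snp_fraction":
        snp_per_win = per_window_counts(snp_by_chrom)
    else:
        snp_per_win = (win["end"] - win["start"]).to_numpy(dtype=float)

    # assign each hotspot to a MAF group via the windows it overlaps
    maf_arr = win["mean_maf"].to_numpy()
    cuts = [maf_arr[groups == g].min() for g in range(n_groups)]
    win_starts = {
        chrom: (
            win.loc[(win["chrom"] == chrom), "start"].to_numpy(),
            win.loc[(win["chrom"] == chrom), "end"].to_numpy(),
            np.flatnonzero((win["chrom"] == chrom).to_numpy()),
        )
        for chrom in win["chrom"].unique()
    }
    hotspot_group = []
    for h in hotspots:
        if h.chrom not in win_starts:
            continue
        starts, ends, idx = win_starts[h.chrom]
        over = idx[(starts < h.end) & (h.start < ends)]
        if len(over) == 0:
            continue
        maf = maf_arr[over].mean()
        g = int(np.searchsorted(cuts, maf, side="right") - 1)
        hotspot_group.append(max(g, 0))
    if not hotspot_group:
        raise ValidationError("no hotspot overlaps a MAF-scored window")

    obs_gwas = counts_in(pos_by_chrom, list(hotspots))
    if statistic == "snp_fraction":
        obs_base = counts_in(snp_by_chrom, list(hotspots))
    else:
        obs_base = sum(h.length for h in hotspots)
    if obs_base == 0:
        raise ValidationError("no SNPs in hotspot regions")
    observed = obs_gwas / obs_base

    pool_idx = {g: np.flatnonzero(groups == g) for g in set(hotspot_group)}
    for g, idx in pool_idx.items():
        if len(idx) == 0:
            raise ValidationError(f"empty MAF group {g}")
    null = np.zeros(n_sims)
    num = np.zeros(n_sims)
    den = np.zeros(n_sims)
    for g in hotspot_group:
        draws = rng.choice(pool_idx[g], size=n_sims, replace=True)
        num += gwas_per_win[draws]
        den += snp_per_win[draws]
    den[den == 0] = np.nan
    null = num / den
    null = np.nan_to_num(null, nan=0.0)
    r = int((null >= observed).sum())
    null_mean = float(null.mean())
    return EnrichmentResult(
        observed=float(observed),
        null_mean=null_mean,
        fold=float(observed / null_mean) if null_mean else np.inf,
        empirical_p=empirical_p(r, n_sims),
        n_sims=n_sims,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# distance profiles, gene tests, recurrency


def distance_profile(
    anchors: np.ndarray,
    features: FeatureTrack,
    chrom: str,
    max_dist: int = 4000,
    bin: int = 50,
    mode: str = "bp",
) -> pd.DataFrame:
    """Feature abundance in symmetric distance bins around anchors.

    Bins run from -max_dist to +max_dist; the value of a bin is feature
    bp (``mode="bp"``) or entry-start count (``mode="count"``) per
    anchor per bin-bp.
    """
    if max_dist % bin:
        raise ValidationError("bin must divide max_dist")
    anchors = np.sort(np.asarray(anchors, dtype=np.int64))
    edges = np.arange(-max_dist, max_dist + bin, bin)
    acc = np.zeros(len(edges) - 1)
    sub = features.entries[features.entries["chrom"] == chrom]
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    for a in anchors:
        hi = np.searchsorted(starts, a + max_dist, side="left")
        for s, e in zip(starts[:hi], ends[:hi]):
            if e <= a - max_dist:
                continue
            if mode == "count":
                b = (s - a + max_dist) // bin
                if 0 <= b < len(acc):
                    acc[b] += 1
                continue
            for b in range(len(acc)):
                b_lo = a + edges[b]
                b_hi = a + edges[b + 1]
                acc[b] += max(0, min(e, b_hi) - max(s, b_lo))
    n = max(len(anchors), 1)
    return pd.DataFrame(
        {"offset": edges[:-1], "value": acc / n / bin}
    )


def gene_cluster_cnvt_test(
    genes: pd.DataFrame,
    clusters: Sequence[GenomicInterval],
    cnvt_breakpoints: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene chi-square for CNVT-breakpoint excess in cluster segments.

    Expected cluster-segment count = (gene's total breakpoints) x
    (fraction of gene bp covered by clusters); a 1-df chi-square
    compares observed vs expected in the segment and its complement.
    Bonferroni multiplies by the number of genes tested (capped at 1).
    ``genes``: columns ``gene, chrom, start, end``; breakpoints:
    ``chrom, pos``.
    """
    cl = merge_intervals(clusters)
    rows = []
    for g in genes.itertuples(index=False):
        giv = GenomicInterval(g.chrom, int(g.start), int(g.end))
        seg_bp = sum(
            max(0, min(c.end, giv.end) - max(c.start, giv.start))
            for c in cl
            if c.chrom == giv.chrom
        )
        if seg_bp == 0:
            continue
        bp = cnvt_breakpoints[cnvt_breakpoints["chrom"] == g.chrom]
        pos = bp["pos"].to_numpy()
        in_gene = pos[(pos >= giv.start) & (pos < giv.end)]
        total = len(in_gene)
        if total == 0:
            continue  # genes without breakpoints are skipped
        in_seg = 0
        for c in cl:
            if c.chrom != giv.chrom:
                continue
            s, e = max(c.start, giv.start), min(c.end, giv.end)
            if e > s:
                in_seg += int(((in_gene >= s) & (in_gene < e)).sum())
        frac = seg_bp / giv.length
        exp_seg = total * frac
        exp_out = total - exp_seg
        obs_out = total - in_seg
        if exp_seg == 0 or exp_out == 0:
            continue
        chi2 = (in_seg - exp_seg) ** 2 / exp_seg + (obs_out - exp_out) ** 2 / exp_out
        p = float(sps.chi2.sf(chi2, df=1))
        rows.append(
            (g.gene, total, in_seg, exp_seg, chi2, p,
             "enriched" if in_seg > exp_seg else "depleted")
        )
    df = pd.DataFrame(
        rows,
        columns=["gene", "n_breakpoints", "observed", "expected", "chi2", "p", "direction"],
    )
    if len(df):
        df["p_bonferroni"] = np.minimum(df["p"] * len(df), 1.0)
    else:
        df["p_bonferroni"] = pd.Series(dtype=float)
    return df


def breakpoint_recurrency(
    breakpoints: pd.DataFrame,
    regions: Sequence[GenomicInterval],
    resolution: int = 1000,
    min_samples: int = 2,
) -> float:
    """Fraction of region-resident breakpoints at recurrent sites.

    A site (position rounded to ``resolution``) is recurrent when
    breakpoints from at least ``min_samples`` distinct samples fall on
    it.  ``breakpoints``: columns ``chrom, pos, sample``.
    """
    keep = np.zeros(len(breakpoints), dtype=bool)
    for chrom, sub in breakpoints.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        m = np.zeros(len(sub), dtype=bool)
        for r in regions:
            if r.chrom == chrom:
                m |= (pos >= r.start) & (pos < r.end)
        keep[sub.index.to_numpy()] = m
    inside = breakpoints[keep]
    if len(inside) == 0:
        return 0.0
    sites = inside.assign(site=inside["pos"] // resolution)
    n_samples = sites.groupby(["chrom", "site"])["sample"].nunique()
    recurrent = n_samples[n_samples >= min_samples].reset_index()[["chrom", "site"]]
    rec_set = set(map(tuple, recurrent.to_numpy()))
    is_rec = [
        (c, s) in rec_set for c, s in zip(sites["chrom"], sites["site"])
    ]
    return float(np.mean(is_rec))
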