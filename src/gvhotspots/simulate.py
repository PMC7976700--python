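"""Seeded synthetic genome bundles with planted, recoverable truth.

The generator emulates every input the pipeline consumes — a zoned
genome, germline variant catalogs with planted high-density blocks, a
four-peak CNV length mixture, per-site population DAF / |nSL| / phyloP
tables with planted selection windows, six-phase replication scores for
15 pseudo cell lines, gene models, MAF-ascertained GWAS SNP subsets and
somatic breakpoints with recurrent sites — and records what it planted
in a truth table so recovery can be measured.

Design notes
------------
* Planted GV hotspots are trapezoid density bumps: a uniform core at
  ``fold`` times the background rate with linear tapers on both flanks.
  Soft edges mirror real hotspots and make recovery well-posed: the
  recruitment cutoff settles somewhere on the monotone taper, so calls
  stay contiguous and budget noise only shifts their edges.  The truth
  interval of a plant is its full-width-at-half-maximum region, and the
  core width per zone is sized so the 5% recruitment budget is spent
  roughly down to the half-maximum.
* Background per-population DAF follows a Balding-Nichols model: an
  ancestral frequency p0 ~ Beta(0.5, 2.5) (a 1/x-like neutral spectrum)
  with per-population Beta noise at F = 0.05.  Planted sweep windows use
  DAF ~ Beta(60, 1) (about 0.98) shared across populations (mean-DAF
  signal) or confined to one population (|dDAF| signal).
* Planted selection windows are placed at random positions, so their
  informative-site counts follow the background distribution and they
  spread across all matching deciles at roughly the earmark fraction.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as gio
from .catalog import SizeClassBounds, VariantCatalog
from .intervals import (
    GapTrack,
    GenomicInterval,
    ValidationError,
    ZonePartition,
    ZONE_LABELS,
    merge_intervals,
)
from .repliseq import PHASES
from .selection import POPULATIONS


@dataclass
class CnvMixture:
    """Four log-normal components whose modes straddle the size cuts."""

    log10_modes: tuple[float, ...] = (1.3, 2.4, 3.7, 4.7)
    log10_sigma: float = 0.18
    weights: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if list(self.log10_modes) != sorted(self.log10_modes):
            raise ValidationError("mixture modes must be increasing")
        if abs(sum(self.weights) - 1.0) > 1e-9 or len(self.weights) != len(self.log10_modes):
            raise ValidationError("mixture weights must match modes and sum to 1")


@dataclass
class GwasModel:
    """Logistic MAF-dependent ascertainment with a hotspot boost."""

    intercept: float = -4.0
    maf_slope: float = 4.0
    hotspot_boost: float = 9.0  # inclusion prob multiplied by (1 + boost) inside


@dataclass
class SimConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    zone_window: int = 500_000
    zone_proportions: tuple[float, float, float] = (0.451, 0.311, 0.238)
    gap_width: int = 50_000
    # background anchor rates per bp
    rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "SNP": 0.01,
            "SID": 0.01,
            "MST": 5e-5,
            "CNV": 0.04,
            "SDP": 2e-4,
        }
    )
    cnv_mixture: CnvMixture = field(default_factory=CnvMixture)
    # planted GV hotspots: kind -> (core fold over background, plants per zone)
    gv_plants: Mapping[str, tuple[float, tuple[int, int, int]]] = field(
        default_factory=lambda: {
            "SNP": (10.0, (3, 2, 2)),
            "SID": (10.0, (3, 2, 2)),
            "MCNV": (10.0, (3, 2, 2)),
        }
    )
    plant_taper: int = 4_000  # linear density taper width per flank, bp
    #: budget design depth: the recruitment cutoff is designed to land at
    #: this fraction of the core fold on the taper — centred between the
    #: core's downward Poisson excursions and background density spikes,
    #: so budget noise moves call edges along the taper rather than into
    #: background or into the noisy core.
    plant_depth: float = 0.5
    target_fraction: float = 0.05
    # selection plants: runs of consecutive 1-kb windows per metric
    possel_runs_per_metric: int = 75
    negsel_runs: int = 30
    run_windows: int = 7
    sweep_beta: tuple[float, float] = (60.0, 1.0)  # DAF ~ 0.98
    nsl_effect: tuple[float, float] = (5.0, 0.4)
    phylop_effect: tuple[float, float] = (4.0, 0.5)
    # population model
    p0_beta: tuple[float, float] = (0.5, 2.5)
    hotspot_p0_beta: tuple[float, float] = (1.2, 2.8)  # elevated MAF in GV plants
    fst: float = 0.05
    nsl_fraction: float = 0.6  # fraction of SNPs with an nSL value
    n_haplotypes: int = 100
    # repli-seq
    n_cell_lines: int = 15
    phase_block_windows: tuple[int, int] = (50, 300)
    repli_score_true: tuple[float, float] = (70.0, 5.0)
    repli_score_other: tuple[float, float] = (20.0, 5.0)
    repli_dropout: float = 0.25
    repli_tie_rate: float = 0.01
    # genes / somatic
    n_genes: int = 120
    gene_length: tuple[int, int] = (20_000, 100_000)
    cnvt_rate: float = 3e-4  # background breakpoints per bp
    n_cnvt_samples: int = 40
    n_recurrent_sites: int = 20
    recurrent_site_samples: tuple[int, int] = (5, 10)
    gwas: GwasModel = field(default_factory=GwasModel)
    n_exome_targets: int = 50
    exome_target_width: int = 2_000
    n_balsel_regions: int = 4
    balsel_width: tuple[int, int] = (5_000, 20_000)


@dataclass
class TruthTable:
    gv_hotspots: dict[str, list[GenomicInterval]]
    possel_windows: dict[str, list[GenomicInterval]]
    negsel_windows: list[GenomicInterval]
    cluster_sites: list[GenomicInterval]
    phase_blocks: list[tuple[GenomicInterval, str]]
    recurrent_sites: list[tuple[str, int]]
    gwas_params: dict

    @property
    def possel_union(self) -> list[GenomicInterval]:
        return merge_intervals(
            [iv for ivs in self.possel_windows.values() for iv in ivs],
            merge_bookended=True,
        )


@dataclass
class SyntheticBundle:
    config: SimConfig
    zones: ZonePartition
    catalog: VariantCatalog
    sites: pd.DataFrame
    repliseq: dict[str, pd.DataFrame]
    genes: pd.DataFrame
    gwas: pd.DataFrame
    cnvt: pd.DataFrame
    balancing: dict[str, list[GenomicInterval]]
    exome_targets: list[GenomicInterval]
    truth: TruthTable

    @property
    def snp_positions(self) -> pd.DataFrame:
        return self.sites[["chrom", "pos"]].copy()

    def write(self, outdir: str | os.PathLike) -> None:
        """Emit the bundle as plain-text standard-format files."""
        outdir = str(outdir)
        os.makedirs(outdir, exist_ok=True)
        gio.write_zones_bed(os.path.join(outdir, "zones.bed"), self.zones)
        gio.write_bed(os.path.join(outdir, "gaps.bed"), self.zones.gaps.gaps)
        _write_snp_vcf(os.path.join(outdir, "snps.vcf"), self.sites)
        for kind in ("SID", "MST", "CNV", "SDP"):
            df = self.catalog.df[self.catalog.df["kind"] == kind]
            out = pd.DataFrame(
                {
                    "chrom": df["chrom"],
                    "start": df["start"] + 1,  # 1-based closed
                    "end": df["end"],
                }
            )
            if kind == "CNV":
                out["size_class"] = df["size_class"].to_numpy()
            gio.write_tsv(os.path.join(outdir, f"{kind.lower()}.tsv"), out)
        gio.write_tsv(
            os.path.join(outdir, "sites.tsv"),
            self.sites.assign(pos=self.sites["pos"] + 1),
        )
        for line, table in self.repliseq.items():
            gio.write_tsv(os.path.join(outdir, f"repliseq_{line}.tsv"), table)
        gio.write_bed(
            os.path.join(outdir, "genes.bed"),
            [GenomicInterval(g.chrom, int(g.start), int(g.end)) for g in self.genes.itertuples()],
            names=list(self.genes["gene"]),
        )
        gio.write_tsv(
            os.path.join(outdir, "gwas.tsv"), self.gwas.assign(pos=self.gwas["pos"] + 1)
        )
        gio.write_tsv(
            os.path.join(outdir, "cnvt.tsv"), self.cnvt.assign(pos=self.cnvt["pos"] + 1)
        )
        for key, regions in self.balancing.items():
            gio.write_bed(os.path.join(outdir, f"balsel_{key}.bed"), regions)
        gio.write_bed(os.path.join(outdir, "exome_targets.bed"), self.exome_targets)


def _write_snp_vcf(path: str, sites: pd.DataFrame) -> None:
    pops = [p for p in POPULATIONS if f"daf_{p}" in sites.columns]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
        for p in pops:
            fh.write(
                f'##INFO=<ID=AF_{p},Number=A,Type=Float,Description="{p} derived allele frequency">\n'
            )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in sites.itertuples(index=False):
            af = np.mean([getattr(r, f"daf_{p}") for p in pops])
            info = f"AF={af:.4f};" + ";".join(
                f"AF_{p}={getattr(r, f'daf_{p}'):.4f}" for p in pops
            )
            fh.write(f"{r.chrom}\t{r.pos + 1}\t.\tA\tG\t.\tPASS\t{info}\n")


# ---------------------------------------------------------------------------
# placement helpers


def _overlaps_any(iv: GenomicInterval, occupied: list[GenomicInterval]) -> bool:
    return any(iv.overlaps(o) for o in occupied)


def _place(
    width: int,
    host: GenomicInterval,
    occupied: list[GenomicInterval],
    rng: np.random.Generator,
    margin: int = 25_000,
    tries: int = 200,
) -> GenomicInterval | None:
    lo = host.start + margin
    hi = host.end - margin - width
    if hi <= lo:
        return None
    for _ in range(tries):
        s = int(rng.integers(lo, hi))
        iv = GenomicInterval(host.chrom, s, s + width)
        if not _overlaps_any(iv, occupied):
            return iv
    return None


def _uniform_positions(
    blocks: list[GenomicInterval], n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(chrom codes, positions) of n points uniform over blocks."""
    if n == 0:
        return np.array([], dtype="<U8"), np.array([], dtype=np.int64)
    lens = np.array([b.length for b in blocks], dtype=np.int64)
    cum = np.cumsum(lens)
    u = rng.integers(cum[-1], size=n)
    b = np.searchsorted(cum, u, side="right")
    offset = u - (cum - lens)[b]
    pos = np.array([blocks[i].start for i in b]) + offset
    chroms = np.array([blocks[i].chrom for i in b])
    return chroms, pos


# ---------------------------------------------------------------------------
# generators


def _make_zones(config: SimConfig, rng: np.random.Generator) -> ZonePartition:
    n_win = config.n_chroms * (config.chrom_length // config.zone_window)
    counts = [int(round(p * n_win)) for p in config.zone_proportions[:2]]
    counts.append(n_win - sum(counts))
    labels = np.repeat(ZONE_LABELS, counts)
    rng.shuffle(labels)
    windows = []
    i = 0
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        for s in range(0, config.chrom_length, config.zone_window):
            windows.append(
                (GenomicInterval(chrom, s, s + config.zone_window), str(labels[i]))
            )
            i += 1
    # one assembly gap per chromosome, clear of zone-window edges
    gaps = []
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        w = int(rng.integers(0, config.chrom_length // config.zone_window))
        s = w * config.zone_window + int(
            rng.integers(100_000, config.zone_window - config.gap_width - 100_000)
        )
        gaps.append(GenomicInterval(chrom, s, s + config.gap_width))
    return ZonePartition(windows=windows, gaps=GapTrack(gaps))


@dataclass(frozen=True)
class GVPlant:
    """A trapezoid density bump: uniform core with linear taper flanks."""

    kind: str
    core: GenomicInterval
    taper: int
    fold: float

    @property
    def half_width(self) -> int:
        """Distance from the core edge to the half-maximum density."""
        return int(round(self.taper * self.fold / (2.0 * (self.fold - 1.0))))

    @property
    def truth(self) -> GenomicInterval:
        """Full-width-at-half-maximum region: the planted hotspot."""
        return GenomicInterval(
            self.core.chrom,
            self.core.start - self.half_width,
            self.core.end + self.half_width,
        )

    @property
    def outer(self) -> GenomicInterval:
        return GenomicInterval(
            self.core.chrom, self.core.start - self.taper, self.core.end + self.taper
        )


def _core_width(
    config: SimConfig, zone_len: int, fold: float, n_plants: int
) -> int:
    """Core width so the 5% budget reaches ``plant_depth`` x fold.

    Solves budget = covered unique anchors at the design cut.  The
    budget is the target fraction of the zone total (background plus
    planted extras).  Coverage at a cut spans the cores plus the taper
    down to the cut position *plus one scan-window width*, because each
    recruited window reaches that much further out.
    """
    t, wt, q = config.target_fraction, float(config.plant_taper), config.plant_depth
    width = 1000.0  # scan window reach beyond the lowest recruited step
    y_cut = wt * (1.0 - q) * fold / (fold - 1.0)
    y_cov = min(y_cut + width, wt)
    g = fold * y_cov - (fold - 1.0) * y_cov**2 / (2.0 * wt)
    num = t * zone_len + n_plants * (t * (fold - 1.0) * wt - 2.0 * g)
    den = n_plants * (fold - t * (fold - 1.0))
    wc = num / den
    if wc < 1000:
        raise ValidationError(
            "infeasible plant plan: core width under one window"
        )
    return int(wc)


def _plant_extra_positions(
    plant: GVPlant, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Extra anchor positions realising the trapezoid bump."""
    out = []
    n_core = rng.poisson((plant.fold - 1.0) * rate * plant.core.length)
    out.append(rng.integers(plant.core.start, plant.core.end, size=n_core))
    n_side = rng.poisson((plant.fold - 1.0) * rate * plant.taper / 2.0)
    for sign, edge in ((-1, plant.core.start), (+1, plant.core.end)):
        z = 1.0 - np.sqrt(1.0 - rng.random(n_side))  # pdf ~ (1 - z)
        y = np.floor(z * plant.taper).astype(np.int64)
        out.append(edge + sign * (y + (1 if sign < 0 else 0)))
    return np.concatenate(out)


def _plan_gv_plants(
    config: SimConfig, zones: ZonePartition, rng: np.random.Generator
) -> dict[str, list[GVPlant]]:
    occupied: list[GenomicInterval] = list(zones.gaps.gaps)
    plants: dict[str, list[GVPlant]] = {}
    zone_wins = {
        label: [iv for iv, lab in zones.windows if lab == label] for label in ZONE_LABELS
    }
    zone_len = {label: sum(iv.length for iv in zone_wins[label]) for label in ZONE_LABELS}
    for kind, (fold, per_zone) in config.gv_plants.items():
        plants[kind] = []
        for label, n_plants in zip(ZONE_LABELS, per_zone):
            if n_plants == 0:
                continue
            wc = _core_width(config, zone_len[label], fold, n_plants)
            placed = 0
            hosts = list(zone_wins[label])
            rng.shuffle(hosts)
            for host in hosts * 4:
                if placed >= n_plants:
                    break
                outer = _place(wc + 2 * config.plant_taper, host, occupied, rng)
                if outer is not None:
                    core = GenomicInterval(
                        outer.chrom,
                        outer.start + config.plant_taper,
                        outer.end - config.plant_taper,
                    )
                    plants[kind].append(GVPlant(kind, core, config.plant_taper, fold))
                    occupied.append(outer)
                    placed += 1
            if placed < n_plants:
                raise ValidationError(
                    f"could not place {n_plants} {kind} plants in {label} zones"
                )
    # co-locate one plant per non-SNP kind with an SNP plant so that
    # planted hotspot clusters exist.  Plants are placed zone-by-zone in
    # ZONE_LABELS order, so index 0 of every kind sits in a Genic window.
    snp_plants = plants.get("SNP", [])
    for j, kind in enumerate(k for k in sorted(plants) if k != "SNP"):
        if not snp_plants or not plants[kind]:
            continue
        anchor = snp_plants[j % len(snp_plants)]
        moved = plants[kind][0]
        centre = anchor.core.start + anchor.core.length // 2
        s = max(centre - moved.core.length // 2, moved.taper)
        plants[kind][0] = GVPlant(
            kind,
            GenomicInterval(anchor.core.chrom, s, s + moved.core.length),
            moved.taper,
            moved.fold,
        )
    return plants


def _plan_selection_runs(
    config: SimConfig,
    zones: ZonePartition,
    occupied: list[GenomicInterval],
    rng: np.random.Generator,
) -> tuple[dict[str, list[GenomicInterval]], list[GenomicInterval]]:
    analyzed = zones.analyzed_space
    blocks = [iv for iv in analyzed if iv.length >= (config.run_windows + 2) * 1000]
    occ = list(occupied)

    def draw_runs(n_runs: int) -> list[GenomicInterval]:
        out = []
        tries = 0
        while len(out) < n_runs and tries < n_runs * 500:
            tries += 1
            b = blocks[int(rng.integers(len(blocks)))]
            # align to the 1-kb selection tiling
            k_lo = -(-b.start // 1000)
            k_hi = b.end // 1000 - config.run_windows
            if k_hi <= k_lo:
                continue
            k = int(rng.integers(k_lo, k_hi))
            iv = GenomicInterval(b.chrom, k * 1000, (k + config.run_windows) * 1000)
            if not _overlaps_any(iv, occ):
                out.append(iv)
                occ.append(iv)
        if len(out) < n_runs:
            raise ValidationError("could not place selection runs")
        return out

    possel = {
        metric: draw_runs(config.possel_runs_per_metric)
        for metric in ("mean_daf", "delta_daf", "mean_abs_nsl")
    }
    negsel = draw_runs(config.negsel_runs)
    return possel, negsel


def simulate_cnv_lengths(
    n: int, mixture: CnvMixture, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample CNV lengths (bp) and their component ids from the mixture."""
    comp = rng.choice(len(mixture.weights), size=n, p=mixture.weights)
    log10 = rng.normal(np.asarray(mixture.log10_modes)[comp], mixture.log10_sigma)
    lengths = np.maximum(np.round(10**log10).astype(np.int64), 6)
    return lengths, comp


def _germline_catalog(
    config: SimConfig,
    zones: ZonePartition,
    plants: dict[str, list[GenomicInterval]],
    rng: np.random.Generator,
) -> VariantCatalog:
    analyzed = zones.analyzed_space
    total_bp = sum(iv.length for iv in analyzed)
    frames = []

    def interval_frame(chroms, starts, lengths, kind, size_class=None):
        return pd.DataFrame(
            {
                "chrom": chroms,
                "start": starts,
                "end": starts + lengths,
                "kind": kind,
                "maf": np.nan,
                "size_class": size_class,
                "sample": None,
            }
        )

    # SNP positions are generated with the site table (they need DAF);
    # here we make SID / MST / CNV / SDP.
    for kind in ("SID", "MST", "SDP"):
        n = rng.poisson(config.rates[kind] * total_bp)
        chroms, starts = _uniform_positions(analyzed, n, rng)
        if kind == "SID":
            lengths = rng.integers(1, 50, size=n)
        elif kind == "MST":
            lengths = rng.integers(20, 200, size=n)
        else:
            lengths = rng.integers(10_000, 50_000, size=n)
        frames.append(interval_frame(chroms, starts, lengths, kind))
        # planted extra entries
        for plant in plants.get(kind, []):
            pos = _plant_extra_positions(plant, config.rates[kind], rng)
            lens = rng.integers(1, 50, size=len(pos))
            frames.append(
                interval_frame(np.repeat(plant.core.chrom, len(pos)), pos, lens, kind)
            )

    n_cnv = rng.poisson(config.rates["CNV"] * total_bp)
    chroms, starts = _uniform_positions(analyzed, n_cnv, rng)
    lengths, _ = simulate_cnv_lengths(n_cnv, config.cnv_mixture, rng)
    frames.append(interval_frame(chroms, starts, lengths, "CNV"))
    mcnv_rate = config.rates["CNV"] * config.cnv_mixture.weights[1]
    for plant in plants.get("MCNV", []):
        pos = _plant_extra_positions(plant, mcnv_rate, rng)
        lens = np.clip(
            np.round(
                10 ** rng.normal(config.cnv_mixture.log10_modes[1], 0.1, size=len(pos))
            ).astype(np.int64),
            80,
            900,
        )
        frames.append(
            interval_frame(np.repeat(plant.core.chrom, len(pos)), pos, lens, "CNV")
        )

    df = pd.concat(frames, ignore_index=True)
    cat = VariantCatalog(df, provenance="synthetic bundle")
    return cat.with_size_classes(SizeClassBounds())


def _site_table(
    config: SimConfig,
    zones: ZonePartition,
    plants: dict[str, list[GVPlant]],
    possel: dict[str, list[GenomicInterval]],
    negsel: list[GenomicInterval],
    rng: np.random.Generator,
) -> pd.DataFrame:
    analyzed = zones.analyzed_space
    total_bp = sum(iv.length for iv in analyzed)
    n_bg = rng.poisson(config.rates["SNP"] * total_bp)
    chroms, pos = _uniform_positions(analyzed, n_bg, rng)
    extra_c, extra_p = [], []
    for plant in plants.get("SNP", []):
        p = _plant_extra_positions(plant, config.rates["SNP"], rng)
        extra_c.append(np.repeat(plant.core.chrom, len(p)))
        extra_p.append(p)
    if extra_c:
        chroms = np.concatenate([chroms, *extra_c])
        pos = np.concatenate([pos, *extra_p])
    order = np.lexsort((pos, chroms))
    chroms, pos = chroms[order], pos[order]
    n = len(pos)

    def in_any(ivs: list[GenomicInterval]) -> np.ndarray:
        mask = np.zeros(n, dtype=bool)
        for iv in ivs:
            mask |= (chroms == iv.chrom) & (pos >= iv.start) & (pos < iv.end)
        return mask

    gv_union = [p.outer for ps in plants.values() for p in ps]
    in_gv = in_any(gv_union)

    a0, b0 = config.p0_beta
    ah, bh = config.hotspot_p0_beta
    p0 = np.where(in_gv, rng.beta(ah, bh, size=n), rng.beta(a0, b0, size=n))
    p0 = np.clip(p0, 0.01, 0.99)
    c = (1.0 - config.fst) / config.fst
    daf = {
        popn: rng.beta(p0 * c, (1.0 - p0) * c) for popn in POPULATIONS
    }

    sa, sb = config.sweep_beta
    in_daf = in_any(possel["mean_daf"])
    for popn in POPULATIONS:
        swept = rng.beta(sa, sb, size=int(in_daf.sum()))
        daf[popn] = daf[popn].copy()
        daf[popn][in_daf] = swept
    in_delta = in_any(possel["delta_daf"])
    daf[POPULATIONS[0]][in_delta] = rng.beta(sa, sb, size=int(in_delta.sum()))

    nsl = np.where(
        rng.random(n) < config.nsl_fraction, rng.normal(0.0, 1.0, size=n), np.nan
    )
    in_nsl = in_any(possel["mean_abs_nsl"])
    mu, sd = config.nsl_effect
    signs = rng.choice([-1.0, 1.0], size=int(in_nsl.sum()))
    nsl[in_nsl] = signs * rng.normal(mu, sd, size=int(in_nsl.sum()))

    phylop = rng.normal(0.0, 1.0, size=n)
    in_neg = in_any(negsel)
    pmu, psd = config.phylop_effect
    phylop[in_neg] = rng.normal(pmu, psd, size=int(in_neg.sum()))

    daf_global = np.mean([daf[popn] for popn in POPULATIONS], axis=0)
    n_alt = np.clip(
        np.round(daf_global * config.n_haplotypes), 1, config.n_haplotypes - 1
    ).astype(int)
    # planted low-diversity windows: almost-fixed sites
    n_alt[in_neg] = 1
    maf = np.minimum(daf_global, 1.0 - daf_global)

    sites = pd.DataFrame({"chrom": chroms, "pos": pos})
    for popn in POPULATIONS:
        sites[f"daf_{popn}"] = daf[popn]
    sites["nsl"] = nsl
    sites["phylop"] = phylop
    sites["maf"] = maf
    sites["n_alt"] = n_alt
    sites["n_total"] = config.n_haplotypes
    return sites


def _repliseq_tables(
    config: SimConfig, zones: ZonePartition, rng: np.random.Generator
) -> tuple[dict[str, pd.DataFrame], list[tuple[GenomicInterval, str]]]:
    frames = {}
    # block-structured true phases on the 1-kb tiling
    blocks: list[tuple[GenomicInterval, str]] = []
    tiling = []
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        n_win = config.chrom_length // 1000
        k = 0
        while k < n_win:
            size = int(rng.integers(*config.phase_block_windows))
            size = min(size, n_win - k)
            phase = PHASES[int(rng.integers(len(PHASES)))]
            blocks.append(
                (GenomicInterval(chrom, k * 1000, (k + size) * 1000), phase)
            )
            k += size
        tiling.append(
            pd.DataFrame({"chrom": chrom, "start": np.arange(n_win) * 1000})
        )
    tiling = pd.concat(tiling, ignore_index=True)
    true_phase = np.empty(len(tiling), dtype=object)
    for iv, phase in blocks:
        sel = (tiling["chrom"] == iv.chrom) & (tiling["start"] >= iv.start) & (
            tiling["start"] < iv.end
        )
        true_phase[sel.to_numpy()] = phase
    phase_idx = np.array([PHASES.index(p) for p in true_phase])

    mu_t, sd_t = config.repli_score_true
    mu_o, sd_o = config.repli_score_other
    n = len(tiling)
    for line_i in range(config.n_cell_lines):
        line = f"CL{line_i + 1:02d}"
        scores = rng.normal(mu_o, sd_o, size=(n, len(PHASES)))
        scores[np.arange(n), phase_idx] = rng.normal(mu_t, sd_t, size=n)
        drop = rng.random(n) < config.repli_dropout
        scores[drop] = np.nan
        tie = (~drop) & (rng.random(n) < config.repli_tie_rate)
        if tie.any():
            rows = np.flatnonzero(tie)
            alt = (phase_idx[rows] + 1 + rng.integers(0, len(PHASES) - 1, size=len(rows))) % len(PHASES)
            scores[rows, alt] = scores[rows, phase_idx[rows]]
        t = tiling.copy()
        for j, p in enumerate(PHASES):
            t[p] = np.round(scores[:, j], 3)
        frames[line] = t
    return frames, blocks


def _genes(config: SimConfig, zones: ZonePartition, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    per_chrom = config.n_genes // config.n_chroms
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        starts = np.sort(
            rng.choice(
                np.arange(0, config.chrom_length - config.gene_length[1], 10_000),
                size=per_chrom,
                replace=False,
            )
        )
        for i, s in enumerate(starts):
            length = int(rng.integers(*config.gene_length))
            rows.append((f"G{c:01d}{i:04d}", chrom, int(s), int(s) + length))
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


def simulate_gwas_ascertainment(
    snps: pd.DataFrame,
    hotspot_intervals: Sequence[GenomicInterval],
    model: GwasModel,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Subset SNPs into a GWAS catalog with MAF-dependent ascertainment.

    Inclusion probability = sigmoid(intercept + slope*MAF), multiplied
    by (1 + hotspot_boost) inside hotspot intervals (capped at 1).
    """
    if snps["maf"].isna().any():
        raise ValidationError("every SNP needs a MAF for GWAS ascertainment")
    maf = snps["maf"].to_numpy(dtype=float)
    prob = 1.0 / (1.0 + np.exp(-(model.intercept + model.maf_slope * maf)))
    inside = np.zeros(len(snps), dtype=bool)
    pos = snps["pos"].to_numpy()
    chroms = snps["chrom"].to_numpy()
    for iv in hotspot_intervals:
        inside |= (chroms == iv.chrom) & (pos >= iv.start) & (pos < iv.end)
    prob = np.clip(prob * np.where(inside, 1.0 + model.hotspot_boost, 1.0), 0, 1)
    keep = rng.random(len(snps)) < prob
    return snps.loc[keep, ["chrom", "pos", "maf"]].reset_index(drop=True)


def _cnvt_breakpoints(
    config: SimConfig,
    zones: ZonePartition,
    cluster_sites: list[GenomicInterval],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, list[tuple[str, int]]]:
    analyzed = zones.analyzed_space
    total_bp = sum(iv.length for iv in analyzed)
    n_bg = rng.poisson(config.cnvt_rate * total_bp)
    chroms, pos = _uniform_positions(analyzed, n_bg, rng)
    samples = [f"S{int(i):03d}" for i in rng.integers(config.n_cnvt_samples, size=n_bg)]
    rows = list(zip(chroms, pos, samples))
    rec_sites: list[tuple[str, int]] = []
    hosts = cluster_sites or analyzed
    for _ in range(config.n_recurrent_sites):
        host = hosts[int(rng.integers(len(hosts)))]
        site = int(rng.integers(host.start, host.end))
        k = int(rng.integers(*config.recurrent_site_samples))
        chosen = rng.choice(config.n_cnvt_samples, size=k, replace=False)
        for s in chosen:
            rows.append((host.chrom, site, f"S{int(s):03d}"))
        rec_sites.append((host.chrom, site))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "sample"]).sort_values(
        ["chrom", "pos"]
    )
    return df.reset_index(drop=True), rec_sites


def simulate_bundle(config: SimConfig | None = None) -> SyntheticBundle:
    """Generate a complete, deterministic input bundle with truth."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)

    zones = _make_zones(config, rng)
    plants = _plan_gv_plants(config, zones, rng)
    occupied = list(zones.gaps.gaps) + [p.outer for ps in plants.values() for p in ps]
    possel, negsel = _plan_selection_runs(config, zones, occupied, rng)

    catalog = _germline_catalog(config, zones, plants, rng)
    sites = _site_table(config, zones, plants, possel, negsel, rng)
    # SNP rows join the catalog so density scans see them
    snp_df = pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "start": sites["pos"],
            "end": sites["pos"] + 1,
            "kind": "SNP",
            "maf": sites["maf"],
            "size_class": None,
            "sample": None,
        }
    )
    catalog = VariantCatalog(
        pd.concat([catalog.df, snp_df], ignore_index=True), provenance="synthetic bundle"
    )

    repliseq, phase_blocks = _repliseq_tables(config, zones, rng)
    genes = _genes(config, zones, rng)

    gv_union = merge_intervals([p.truth for ps in plants.values() for p in ps])
    gwas = simulate_gwas_ascertainment(
        sites[["chrom", "pos", "maf"]],
        gv_union,
        config.gwas,
        rng,
    )

    # planted cluster sites = overlaps between plants of different kinds
    cluster_sites = []
    kinds = list(plants)
    for i, ka in enumerate(kinds):
        for kb in kinds[i + 1 :]:
            for pa in plants[ka]:
                for pb in plants[kb]:
                    a, b = pa.truth, pb.truth
                    if a.overlaps(b):
                        cluster_sites.append(
                            GenomicInterval(
                                a.chrom, max(a.start, b.start), min(a.end, b.end)
                            )
                        )
    cnvt, rec_sites = _cnvt_breakpoints(config, zones, cluster_sites, rng)

    balancing = {}
    analyzed = zones.analyzed_space
    for popn in ("AFR", "EUR"):
        for tf in ("tf0.3", "tf0.4", "tf0.5"):
            regions = []
            for _ in range(config.n_balsel_regions):
                width = int(rng.integers(*config.balsel_width))
                b = analyzed[int(rng.integers(len(analyzed)))]
                if b.length <= width:
                    continue
                s = int(rng.integers(b.start, b.end - width))
                regions.append(GenomicInterval(b.chrom, s, s + width))
            balancing[f"{popn}_{tf}"] = sorted(regions)

    exome_targets = []
    for _ in range(config.n_exome_targets):
        b = analyzed[int(rng.integers(len(analyzed)))]
        if b.length <= config.exome_target_width:
            continue
        s = int(rng.integers(b.start, b.end - config.exome_target_width))
        exome_targets.append(
            GenomicInterval(b.chrom, s, s + config.exome_target_width)
        )

    truth = TruthTable(
        gv_hotspots={k: [p.truth for p in ps] for k, ps in plants.items()},
        possel_windows=possel,
        negsel_windows=negsel,
        cluster_sites=merge_intervals(cluster_sites),
        phase_blocks=phase_blocks,
        recurrent_sites=rec_sites,
        gwas_params={
            "intercept": config.gwas.intercept,
            "maf_slope": config.gwas.maf_slope,
            "hotspot_boost": config.gwas.hotspot_boost,
        },
    )
    return SyntheticBundle(
        config=config,
        zones=zones,
        catalog=catalog,
        sites=sites,
        repliseq=repliseq,
        genes=genes,
        gwas=gwas,
        cnvt=cnvt,
        balancing=balancing,
        exome_targets=sorted(exome_targets),
        truth=truth,
    )
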