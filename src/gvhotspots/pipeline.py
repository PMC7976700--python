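"""End-to-end orchestration of the hotspot / selection / enrichment stages."""
from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import pandas as pd

from . import io as gio
from .catalog import SCAN_KINDS
from .clusters import call_clusters, composition_summary
from .compare import (
    compare_regions_ttest,
    daf_high_fraction,
    population_pairs,
    region_classes,
    region_delta_daf,
)
from .enrichment import maf_matched_enrichment
from .intervals import merge_intervals
from .repliseq import consensus_phases, phase_segments
from .scan import ScanConfig, detect_hotspots
from .selection import (
    SelectionConfig,
    call_selection_hotspots,
    merge_balancing_regions,
    tile_genome_1kb,
    window_selection_stats,
)
from .simulate import SyntheticBundle

log = logging.getLogger("gvhotspots")


@dataclass
class PipelineConfig:
    scan: ScanConfig = field(default_factory=ScanConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    n_sims_gwas: int = 1000
    seed: int = 0
    kinds: tuple[str, ...] = SCAN_KINDS


def run_pipeline(
    bundle: SyntheticBundle, outdir: str | os.PathLike, config: PipelineConfig | None = None
) -> dict:
    """Run every stage on a bundle and write result tables to ``outdir``.

    Stages with missing inputs are skipped with a logged notice.  All
    stochastic stages derive their generators from ``config`` seeds, so
    a rerun with the same bundle and config is identical.
    """
    config = config or PipelineConfig()
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    results: dict = {}

    # --- density hotspots per kind -------------------------------------
    hotspots = {}
    for kind in config.kinds:
        if len(bundle.catalog.subset_kind(kind)) == 0:
            log.info("no %s entries; skipping scan", kind)
            continue
        hotspots[kind] = detect_hotspots(bundle.catalog, bundle.zones, kind, config.scan)
    results["hotspots"] = hotspots
    rows = [
        (h.region.chrom, h.region.start + 1, h.region.end, k, h.zone,
         round(h.d_min_used, 6), h.n_windows_merged)
        for k, hs in hotspots.items()
        for h in hs
    ]
    gio.write_tsv(
        os.path.join(outdir, "hotspots.tsv"),
        pd.DataFrame(rows, columns=["chrom", "start", "end", "kind", "zone", "d_min", "n_windows"]),
    )

    # --- clusters -------------------------------------------------------
    clusters = call_clusters(hotspots)
    results["clusters"] = clusters
    gio.write_tsv(
        os.path.join(outdir, "clusters.tsv"),
        pd.DataFrame(
            [
                (c.region.chrom, c.region.start + 1, c.region.end, c.label, len(c.members))
                for c in clusters
            ],
            columns=["chrom", "start", "end", "composition", "n_members"],
        ),
    )
    gio.write_tsv(os.path.join(outdir, "cluster_compositions.tsv"), composition_summary(clusters))

    # --- selection ------------------------------------------------------
    if len(bundle.sites):
        extents = {c: bundle.zones.chrom_extent(c) for c in bundle.zones.chromosomes}
        windows = tile_genome_1kb(extents)
        stats = window_selection_stats(bundle.sites, windows)
        results["selection_stats"] = stats
        possel = call_selection_hotspots(stats, "PosSel", config.selection)
        negsel = call_selection_hotspots(stats, "NegSel", config.selection)
        balsel = merge_balancing_regions(bundle.balancing.values())
        results["possel"] = possel
        results["negsel"] = negsel
        results["balsel"] = balsel
        gio.write_tsv(
            os.path.join(outdir, "selection_hotspots.tsv"),
            pd.DataFrame(
                [
                    (h.region.chrom, h.region.start + 1, h.region.end, h.mode, h.metric,
                     h.empirical_p, h.n_windows)
                    for h in [*possel, *negsel, *balsel]
                ],
                columns=["chrom", "start", "end", "mode", "metric", "empirical_p", "n_windows"],
            ),
        )
    else:
        log.info("no site table; skipping selection stage")
        stats = None

    # --- replication phases --------------------------------------------
    if bundle.repliseq:
        assignments = consensus_phases(bundle.repliseq)
        segments = phase_segments(assignments)
        results["phase_segments"] = segments
        gio.write_tsv(
            os.path.join(outdir, "phase_segments.tsv"),
            pd.DataFrame(
                [
                    (s.region.chrom, s.region.start + 1, s.region.end, s.phase, s.n_windows)
                    for s in segments
                ],
                columns=["chrom", "start", "end", "phase", "n_windows"],
            ),
        )
    else:
        log.info("no repli-seq tables; skipping phase stage")

    # --- GWAS enrichment -------------------------------------------------
    hotspot_union = merge_intervals(
        [h.region for hs in hotspots.values() for h in hs]
    )
    if len(bundle.gwas) and stats is not None and hotspot_union:
        res = maf_matched_enrichment(
            hotspot_union,
            bundle.gwas,
            stats.dropna(subset=["mean_maf"]),
            snp_positions=bundle.snp_positions,
            n_sims=config.n_sims_gwas,
            seed=config.seed,
        )
        results["gwas_enrichment"] = res
        gio.write_tsv(
            os.path.join(outdir, "gwas_enrichment.tsv"),
            pd.DataFrame(
                [(res.observed, res.null_mean, res.fold, res.empirical_p, res.n_sims, res.seed)],
                columns=["observed", "null_mean", "fold", "p", "n_sims", "seed"],
            ),
        )

    # --- region-class comparisons ----------------------------------------
    if stats is not None and hotspot_union:
        classes = region_classes(
            bundle.zones.analyzed_space,
            hotspot_union,
            [c.region for c in clusters],
        )
        comp_rows = []
        for popn in ("AFR", "EUR"):
            for label, regions in classes.items():
                if regions:
                    frac = daf_high_fraction(regions, bundle.sites, popn)
                    comp_rows.append(("daf_gt_0.95", popn, label, frac))
        for pair in population_pairs()[:3]:
            cl = classes["cluster"]
            non = classes["non-hotspot"]
            if len(cl) >= 2 and len(non) >= 2:
                va = region_delta_daf(cl, bundle.sites, pair)
                vb = region_delta_daf(non, bundle.sites, pair)
                if len(va) >= 2 and len(vb) >= 2:
                    t, p = compare_regions_ttest(va, vb, "greater")
                    comp_rows.append(("delta_daf_t", "-".join(pair), "cluster_vs_non", p))
        gio.write_tsv(
            os.path.join(outdir, "comparisons.tsv"),
            pd.DataFrame(comp_rows, columns=["statistic", "context", "class", "value"]),
        )
        results["comparisons"] = comp_rows

    manifest = {
        "seed": config.seed,
        "scan": asdict(config.scan),
        "selection": asdict(config.selection),
        "n_hotspots": {k: len(v) for k, v in hotspots.items()},
        "n_clusters": len(clusters),
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    results["manifest"] = manifest
    return results
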