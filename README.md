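# gvhotspots

Detection of genetic-variant hotspots and hotspot clusters in a zoned
genome, with selection scans, replication-phase consensus segments and
matched Monte Carlo enrichment statistics.

Genetic variants — SNPs, small indels (SID), microsatellites (MST),
copy-number variants in four size classes (SCNV ≤ 61 bp, MCNV ≤ 952 bp,
LCNV ≤ 15,571 bp, ECNV beyond), and segmental duplications (SDP) — are
distributed unevenly along the genome.  Regions of exceptional variant
density mark sites of genomic instability that both feed adaptive
evolution and concentrate disease-associated variation.  This package
implements, as a tested and reusable library, a density-based scan for
such regions and the downstream statistics that characterise them:

* **Weighted sliding-window scan** — 1-kb windows in 10-bp steps; step
  counts are weighted from 0.5 at the margins to 1.0 at the centre and

  `D_win = Σ w_step·n_step / Σ w_step`.

  Within each zone type (Genic / Proximal / Distal 500-kb windows,
  consumed as input), top-density windows are recruited until they
  cover 5% of the zone's variant entries; the lowest recruited density
  `D_min` then admits zone-crossing windows, and recruited windows
  merge into **hotspots**.  Overlapping hotspots of ≥ 2 distinct kinds
  merge into **hotspot clusters**.
* **Selection hotspots** — per-1-kb-window mean DAF, |ΔDAF| across
  population pairs, |nS_L|, phyloP and nucleotide diversity π; top-5%
  windows are tested against 10,000 windows resampled from the same
  informative-site decile (empirical p = (r+1)/(n+1)) and significant
  runs merge into PosSel-/NegSel-hotspots; balancing-selection regions
  merge into BalSel-hotspots.
* **Replication-time segments** — consensus phase (G1b…G2) per window
  by majority vote over 15 cell lines (> 8 required, ties excluded),
  merged into segments.
* **Enrichment statistics** — Density/Intensity feature levels,
  size-matched region shuffling with empirical p-values, MAF-matched
  GWAS-SNP enrichment, per-gene chi-square tests of somatic CNV
  breakpoints in cluster segments, distance profiles, and breakpoint
  recurrency.
* **Synthetic genomes** — a seeded generator producing every input the
  pipeline consumes with planted, recoverable truth, so all of the
  above is verifiable at desk scale (2 × 5 Mb by default).

## Worked example

```python
from gvhotspots import SimConfig, simulate_bundle, detect_hotspots, call_clusters

bundle = simulate_bundle(SimConfig(seed=1))          # 2 x 5 Mb, planted truth
hotspots = {k: detect_hotspots(bundle.catalog, bundle.zones, k)
            for k in ("SNP", "SID", "MCNV")}
clusters = call_clusters(hotspots)
print({k: len(v) for k, v in hotspots.items()}, len(clusters))
```

prints

```
{'SNP': 7, 'SID': 7, 'MCNV': 8} 2
```

— seven SNP hotspot calls for the seven planted SNP-dense regions (and
likewise for the other kinds), plus two clusters where plants of
different kinds were placed to overlap: the calls of one kind are
merged runs of top-5%-coverage windows, and the clusters are merged
regions of overlapping calls of distinct kinds.  Each call carries its
zone and the `D_min` recruitment threshold that produced it.  The
scripts in `examples/` walk through each capability (hotspot scan,
size classes and clusters, selection hotspots, replication phases,
enrichment tests) and print annotated output.

The command line offers the two end-to-end entry points:

```bash
gvhotspots simulate --seed 1 --out bundle_dir   # write a synthetic bundle
gvhotspots run --seed 1 --out results_dir       # simulate + run all stages
```

## Layout

```
src/gvhotspots/
  intervals.py   coordinate conventions and interval algebra
  io.py          BED / TSV / VCF readers and writers
  catalog.py     variant catalogs, CNV size classes, anchors
  scan.py        weighted sliding-window scan and hotspot calls
  clusters.py    hotspot clusters and composition summaries
  selection.py   window statistics, matched nulls, selection hotspots
  repliseq.py    replication-phase consensus and segments
  enrichment.py  feature levels, shuffling, Monte Carlo, gene tests
  compare.py     region-class population-genetic comparisons
  simulate.py    synthetic bundle generator with truth tables
  pipeline.py    end-to-end orchestration
  cli.py         thin command-line wrapper
```

See `docs/methods.md` for the models, defaults, generator design and
numerical decisions.
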