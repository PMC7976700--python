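# Methods

This note documents the models and procedures implemented in
`gvhotspots`, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical decisions taken
where the underlying method description leaves room.

## Weighted sliding-window density scan

Each autosome is tiled with 1-kb windows advancing in 10-bp steps.
The anchor count `n_step` in each of the 100 steps of a window is
weighted symmetrically: weight 0.5 at the two extreme margins rising in
equal increments of `0.5/49` to 1.0 at the two central steps, and

    D_win = sum(w_step * n_step) / sum(w_step),       sum(w_step) = 75.

Variants are anchored at their start position (SNP, small indels,
microsatellites, short and medium CNVs) or at both breakpoints (long
and extra-long CNVs, segmental duplications, somatic CNVs); a
two-breakpoint entry still counts once in coverage accounting.
The start-position convention for short variants is a documented choice
— the alternative (midpoint) moves anchors by at most half a variant
length, which is below the 10-bp step resolution for most short kinds.

### Zone-stratified recruitment

Genome zones (Genic / Proximal / Distal, 500-kb windows) are consumed
as input.  Within one zone type, sliding windows are split into Part I
(entirely inside the zone union) and Part II (partially inside).
Part I windows are recruited in decreasing `D_win` order until the
**unique** variant entries covered by the union of recruited windows
would exceed 5% of the zone type's entries.  Overlapping sliding
windows share entries, so summing per-window counts would double-count;
the unique-entry reading is used throughout.  The lowest recruited
density is the zone threshold `D_min`; every Part II window with
`D_win >= D_min` is then recruited.  Ties at the recruitment boundary
are resolved all-or-none per tied group, which makes the result
independent of sort order.

Recruited windows from the three zone types are pooled, de-duplicated
(a window recruited through two zone types counts once) and merged
into maximal hotspot regions.  Book-ended windows (10-bp adjacency)
are merged; at the step granularity adjacency is ubiquitous and
treating it as separation would shatter calls into slivers.
Windows with more than half their bases in assembly gaps or outside
the analyzed space are never recruited.

## Hotspot clusters

Clusters are connected components of the strict-overlap graph over
hotspots of all kinds, kept when they contain two or more distinct
kinds.  Book-ended hotspots do not cluster.  Since every edge shares
bases, a component's union is one contiguous interval, which is the
cluster region.

## Selection scans

Selection is evaluated on a fixed non-overlapping 1-kb tiling (the
10-bp sliding grid is a hotspot-boundary device; selection statistics
are per-window summaries and gain nothing from it).  Per window:

* `mean_daf` — mean over SNPs of the site's derived-allele frequency
  averaged across the five populations;
* `delta_daf` — mean over SNPs of the maximum |DAF difference| across
  all population pairs (for two populations this is the plain |dDAF|);
* `mean_abs_nsl` — mean |nSL| over scored sites;
* `phylop` — mean conservation score;
* `pi` — nucleotide diversity, `sum 2*n_alt*(n_total-n_alt) /
  (n_total*(n_total-1)) / window_length`, equal to the mean pairwise
  haplotype difference per bp (verified against an O(n^2) oracle).

Windows in the top 5% of a positive-selection metric (top-5% phyloP or
bottom-5% pi for purifying selection) are earmarked; quantile ties are
all included.  All windows are ranked into ten equal groups (deciles)
by informative-site count, ties taking the lower decile.  Each
candidate is compared with 10,000 windows drawn with replacement from
its own decile, excluding itself; p = (r+1)/(n+1) where r counts draws
at least as extreme.  Because the draws are i.i.d. from a fixed pool,
r is binomial in the pool exceedance fraction and is drawn as such —
distributionally identical to explicit resampling and O(1) per
candidate.  Candidates with p < 0.05 are kept and successive
significant windows merge into selection hotspots.

The decile matching is the procedure's essential control: windows with
few informative sites have high-variance means and dominate raw
quantile tails; comparing them only against equally sparse windows
removes that artefact.

For purifying selection two rules are provided: earmark by either
metric then filter (`negsel_rule="or_filter"`, default) or require
top-phyloP and bottom-pi at once (`"and_quantiles"`); the method
description supports both readings.

Balancing-selection regions are inputs; they are merged across
populations and target frequencies into disjoint BalSel hotspots.

## Replication-phase consensus

Per 1-kb window and cell line, the highest-scoring phase(s) of
G1b/S1/S2/S3/S4/G2 each cast a vote (within-line ties vote multiply;
scores are tabulated values, so ties are exact equality, no epsilon).
The representative phase is the unique modal phase over the 15 cell
lines; windows assessed in fewer than nine lines, or with a tied mode,
are excluded.  Runs of adjacent same-phase windows merge into
segments; exclusions break runs.

## Enrichment statistics

Feature levels are Density (covered bp / region bp) or Intensity
(bp-weighted score / region bp), overlap-clipped to the region.  Folds
are relative to the analyzed-space average.  Significance uses
number- and size-matched random placement of the target regions within
the analyzed space (surrogates may overlap; a strict non-overlap mode
is not needed at the sparsities involved and is not implemented) and
the empirical p-value (r+1)/(n+1), which is never zero.  The
genome-scale default of five million rounds is configurable and all
tests run at 200–10,000 rounds.

GWAS-SNP enrichment matches the null on allele frequency: windows are
split into ten equal groups by mean MAF, each hotspot is assigned the
group of its overlapping windows, and every simulation draws one
window per hotspot from that group.  The default statistic is the GWAS
fraction *of SNPs* (ascertainment rate).  A per-bp density statistic
(`statistic="bp_density"`) is also provided but conflates variant
density with ascertainment: hotspots are SNP-dense by construction, so
a per-bp test is significant even when GWAS discovery depends on MAF
alone, defeating the purpose of the matching.  The per-SNP default
isolates the allele-frequency channel, which is what the matched
design is for.

The gene-level somatic test compares CNVT breakpoint counts inside and
outside a gene's cluster segments with a 1-df chi-square against
expectations proportional to segment bp, Bonferroni-corrected over
genes tested (capped at 1).  Breakpoint recurrency is the fraction of
region-resident breakpoints at sites (1-kb resolution) hit by at least
two distinct samples; resolution and threshold are parameters since
the construction is not standardised.

## Synthetic bundle

The generator produces a 2 x 5 Mb zoned genome (45.1/31.1/23.8%
Genic/Proximal/Distal 500-kb windows, one 50-kb gap per chromosome)
with every input track the pipeline consumes, and a truth table.

**Planted GV hotspots** are trapezoid density bumps: a uniform core at
`fold` times background with 4-kb linear tapers on each flank.  Soft
edges are both more realistic than hard blocks and essential for
well-posed recovery: the 5% recruitment budget always spends itself
somewhere, and on a taper the stopping point slides smoothly along the
flank instead of fragmenting a noisy core or spilling into scattered
background spikes.  The truth interval is the full-width-at-
half-maximum region of the bump.  Core widths per zone are solved so
that the budget — 5% of the zone's entries — is spent down to half the
core fold, accounting for the 1-kb reach of the lowest recruited
window.  Background rates (SNP 0.01/bp, small indels 0.01/bp, CNVs
0.04/bp split over a four-peak log-normal length mixture with modes at
20/250/5,000/50,000 bp) are desk-scale inflations chosen so per-window
Poisson noise is small relative to the planted contrast; relative
rates between kinds are not meant to mirror real catalogs.

**Population DAF** follows a Balding–Nichols model: ancestral
frequency `p0 ~ Beta(0.5, 2.5)` (a 1/x-like neutral frequency
spectrum, most derived alleles rare) and per-population frequencies
Beta-distributed around `p0` with F = 0.05.  This keeps populations
correlated, as real populations are, and keeps the null upper tail of
window-mean DAF thin — a symmetric U-shaped background would make
single-SNP windows look like sweeps.  SNPs inside planted GV hotspots
draw `p0 ~ Beta(1.2, 2.8)` (higher MAF), mirroring the elevated allele
frequencies of hotspot variants and creating the ascertainment
confound the MAF-matched test must absorb.

**Planted selection windows** come in three disjoint sets of 75 runs
of 7 consecutive 1-kb windows, one set per metric: shared sweeps
(all-population DAF ~ Beta(60,1), i.e. about 0.98 — an extreme but
attainable sweep signature), single-population sweeps (|dDAF|), and
elevated |nSL| (N(5, 0.4) at scored sites).  Planted windows sit at
random positions, so their informative-site counts follow the
background distribution and they spread over all deciles at roughly
the 5% earmark fraction — the regime in which the earmark budget is
filled by true signal and the matched-null filter retires spurious
low-count candidates.  About 16% of windows carry some planted signal,
comparable to the double-digit genome fractions such scans label.
Purifying-selection plants (30 runs) elevate phyloP and suppress
diversity (near-fixed sites).

**Other tracks**: six-phase replication scores for 15 pseudo cell
lines with block-structured truth (true phase ~ N(70,5), others
~ N(20,5), 25% per-line dropout, 1% injected within-line ties); gene
models; GWAS ascertainment `sigmoid(-4 + 4*MAF)` times `(1 + 9)`
inside planted hotspots; somatic breakpoints with 20 recurrent sites
placed in planted cluster overlaps; balancing-selection region sets
per population and target frequency; exome-target intervals.

Everything derives from one `numpy` generator seeded by the config, so
bundles are bit-reproducible, and the truth table is recomputable from
`(config, seed)` alone.

### What passing recovery tests does and does not show

The generator has no linkage disequilibrium (|nSL| is simulated, not
computed from haplotypes), no mutation-rate heterogeneity beyond the
plants, Poisson placement rather than clustered variant processes, and
clean rectangular-to-trapezoid hotspots.  Recovery therefore
demonstrates that the implementation performs the defined procedure
correctly and that the procedure detects dense regions of the stated
contrast at desk scale — not that real-genome hotspot counts or widths
would be reproduced, which depend on full-size catalogs this package
does not ship.

## Numerical choices

* Internal coordinates are 0-based half-open; tabular outputs are
  1-based closed; BED stays 0-based.  Chromosome names are opaque.
* Density ties during recruitment: exact float equality defines a tie
  group (densities are ratios of small integers over 75, so genuine
  ties are common and exact).
* Welch (unequal-variance) unpaired one-tailed t tests for
  region-class comparisons; two identical constant samples return
  p = 0.5 by convention (configurable to raise).
* CNV size cuts: Gaussian KDE on log10(length), bandwidth 0.08 log10
  units, peaks above 2% of the maximum, degree-4 polynomial fitted
  between successive peaks, cut at its interior minimum.  The default
  bounds 61/952/15,571 bp are used when no refit is requested.
* Empirical p-values are (r+1)/(n+1) and can never be zero; a reported
  "p = 0" is representable only as p < 1/(n+1).

## Known limitations

* Sex chromosomes, circular chromosomes and alt-contig graphs are out
  of scope; zones and gaps define the analyzed universe.
* The hotspot scan's 5% budget is unconditional: in a zone without any
  dense region the budget still recruits the top background
  fluctuations.  This is the defined behaviour, visible in the
  examples, not a defect — interpretation requires the `D_min`
  thresholds that every call carries.
* `maf_matched_enrichment` draws 1-kb windows as surrogates regardless
  of hotspot width; widths enter only through the per-SNP statistic.
* Genes may overlap each other in the generator; the gene-level test
  treats genes independently, as the chi-square construction does.
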