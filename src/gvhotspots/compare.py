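"""Region-class comparisons of selection signals.

Analyzed space is partitioned into three disjoint classes — cluster
bases, hotspot bases outside clusters, and non-hotspot bases — and
population-genetic summaries (high-DAF SNP fractions, region-level
|dDAF| between population pairs) are compared between classes with
unpaired one-tailed Welch t tests.
"""
from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .intervals import (
    GenomicInterval,
    ValidationError,
    intersect_sets,
    merge_intervals,
    subtract_intervals,
)
from .selection import POPULATIONS


def population_pairs(pops: Sequence[str] = POPULATIONS) -> list[tuple[str, str]]:
    """All unordered population pairs (C(5,2)=10 for the default five)."""
    return list(combinations(pops, 2))


def region_classes(
    analyzed_space: Sequence[GenomicInterval],
    hotspots: Sequence[GenomicInterval],
    clusters: Sequence[GenomicInterval],
) -> dict[str, list[GenomicInterval]]:
    """Disjoint cluster / hotspot / non-hotspot partition of the space.

    Cluster bases take precedence over their member hotspots; the
    hotspot class is hotspot bases outside any cluster; non-hotspot is
    everything else in the analyzed space.
    """
    cl = intersect_sets(clusters, analyzed_space)
    hs = subtract_intervals(intersect_sets(hotspots, analyzed_space), cl)
    non = subtract_intervals(analyzed_space, merge_intervals(list(cl) + list(hs)))
    return {"cluster": cl, "hotspot": hs, "non-hotspot": non}


def _sites_in_regions(sites: pd.DataFrame, regions: Sequence[GenomicInterval]) -> pd.DataFrame:
    masks = []
    for chrom, sub in sites.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        m = np.zeros(len(sub), dtype=bool)
        for r in regions:
            if r.chrom == chrom:
                m |= (pos >= r.start) & (pos < r.end)
        masks.append(pd.Series(m, index=sub.index))
    if not masks:
        return sites.iloc[:0]
    mask = pd.concat(masks).sort_index()
    return sites[mask.to_numpy()]


def daf_high_fraction(
    regions: Sequence[GenomicInterval],
    sites: pd.DataFrame,
    population: str,
    threshold: float = 0.95,
) -> float:
    """Fraction of region SNPs with DAF above ``threshold`` in one
    population (NaN when the regions contain no scored SNP)."""
    col = f"daf_{population}"
    if col not in sites.columns:
        raise ValidationError(f"no DAF column for population {population!r}")
    sub = _sites_in_regions(sites, regions).dropna(subset=[col])
    if len(sub) == 0:
        return float("nan")
    return float((sub[col] > threshold).mean())


def region_delta_daf(
    regions: Sequence[GenomicInterval],
    sites: pd.DataFrame,
    pop_pair: tuple[str, str],
) -> np.ndarray:
    """|mean DAF_pop1 - mean DAF_pop2| per region; empty regions dropped."""
    a, b = (f"daf_{p}" for p in pop_pair)
    for col in (a, b):
        if col not in sites.columns:
            raise ValidationError(f"missing column {col}")
    out = []
    for r in regions:
        sub = _sites_in_regions(sites, [r]).dropna(subset=[a, b])
        if len(sub) == 0:
            continue
        out.append(abs(sub[a].mean() - sub[b].mean()))
    return np.asarray(out)


def compare_regions_ttest(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alternative: str = "greater",
    bonferroni: int = 1,
    on_degenerate: str = "p5",
) -> tuple[float, float]:
    """Unpaired one-tailed Welch t test of a against b.

    Returns (t, p) with p optionally Bonferroni-multiplied (capped at
    1).  Two identical constant samples give p = 0.5 by convention
    (``on_degenerate="p5"``) or raise (``"error"``).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least 2 values")
    if alternative not in ("greater", "less"):
        raise ValidationError("alternative must be greater or less")
    if a.std() == 0 and b.std() == 0 and len(set(a)) == 1 and a[0] == b[0]:
        if on_degenerate == "p5":
            return 0.0, min(0.5 * bonferroni, 1.0)
        raise ValidationError("both groups constant and identical")
    t, p = sps.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return float(t), float(min(p * bonferroni, 1.0))
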