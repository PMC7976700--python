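"""Hotspot clusters: overlapping hotspots of distinct variant kinds.

A cluster is a connected component of the pairwise-overlap graph over
hotspots of all kinds, kept only when it contains at least two distinct
kinds.  Overlap means at least one shared base pair; book-ended
hotspots do not cluster.  Because every edge of the component shares
bases, the union of member regions is one contiguous interval.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .intervals import GenomicInterval
from .scan import HotspotCall


@dataclass
class HotspotCluster:
    region: GenomicInterval
    members: list[HotspotCall]
    composition: tuple[str, ...]  # sorted distinct member kinds

    @property
    def label(self) -> str:
        return "+".join(self.composition) + "-H"


def call_clusters(
    hotspot_sets: Mapping[str, Sequence[HotspotCall]] | Iterable[HotspotCall],
) -> list[HotspotCluster]:
    """Merge overlapping hotspots of different kinds into clusters."""
    if isinstance(hotspot_sets, Mapping):
        hotspots = [h for hs in hotspot_sets.values() for h in hs]
    else:
        hotspots = list(hotspot_sets)
    hotspots.sort(key=lambda h: (h.region.chrom, h.region.start, h.region.end))

    clusters: list[HotspotCluster] = []
    group: list[HotspotCall] = []
    group_end = -1

    def close() -> None:
        if not group:
            return
        kinds = tuple(sorted({h.kind for h in group}))
        if len(kinds) >= 2:
            chrom = group[0].region.chrom
            clusters.append(
                HotspotCluster(
                    region=GenomicInterval(
                        chrom,
                        min(h.region.start for h in group),
                        max(h.region.end for h in group),
                    ),
                    members=list(group),
                    composition=kinds,
                )
            )

    for h in hotspots:
        if group and h.region.chrom == group[0].region.chrom and h.region.start < group_end:
            group.append(h)
            group_end = max(group_end, h.region.end)
        else:
            close()
            group = [h]
            group_end = h.region.end
    close()
    return clusters


def composition_summary(clusters: Sequence[HotspotCluster]) -> pd.DataFrame:
    """Count and total bp per composition label."""
    rows: dict[str, list[int]] = {}
    for c in clusters:
        rows.setdefault(c.label, [0, 0])
        rows[c.label][0] += 1
        rows[c.label][1] += c.region.length
    df = pd.DataFrame(
        [(label, n, bp) for label, (n, bp) in sorted(rows.items())],
        columns=["composition", "count", "total_bp"],
    )
    return df
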