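"""Weighted sliding-window density scan and zone-stratified hotspot calls.

The genome is scanned in 1-kb windows advancing in 10-bp steps.  Counts
in each of the one hundred 10-bp steps of a window are weighted
symmetrically — 0.5 at the extreme margins rising in equal increments to
1.0 at the two central steps — and the weighted density of a window is

    D_win = sum(w_step * n_step) / sum(w_step).

Within each zone type (Genic / Proximal / Distal), windows are split
into Part I (entirely inside the zone union) and Part II (partially
inside).  Part I windows are recruited from the highest density down
until the unique variant entries they cover reach 5% of the zone's total
entries; the lowest recruited density (D_min) then admits every Part II
window with D_win >= D_min.  Recruited windows from the three zone types
are pooled, de-duplicated and merged into maximal hotspot regions.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .catalog import VariantCatalog, kind_anchors
from .intervals import (
    GenomicInterval,
    ValidationError,
    ZonePartition,
    ZONE_LABELS,
)


@dataclass(frozen=True)
class WeightScheme:
    """Symmetric per-step weights for one window."""

    n_steps: int
    w: np.ndarray

    @property
    def total(self) -> float:
        return float(self.w.sum())


def build_weights(n_steps: int = 100) -> WeightScheme:
    """Equal-increment symmetric weights: 0.5 at margins, 1.0 at centre.

    For the default 100 steps the increment between adjacent steps is
    0.5/49 and the weights sum to exactly 75.
    """
    if n_steps < 2 or n_steps % 2 != 0:
        raise ValidationError("n_steps must be even and >= 2")
    half = n_steps // 2
    if half == 1:
        left = np.array([1.0])
    else:
        left = 0.5 + 0.5 * np.arange(half) / (half - 1)
    w = np.concatenate([left, left[::-1]])
    return WeightScheme(n_steps=n_steps, w=w)


def weighted_density(counts: Sequence[float] | np.ndarray, scheme: WeightScheme) -> float:
    """``sum(w*n)/sum(w)`` for one window's per-step counts."""
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (scheme.n_steps,):
        raise ValidationError(
            f"expected {scheme.n_steps} step counts, got {counts.shape}"
        )
    return float(np.dot(counts, scheme.w) / scheme.total)


@dataclass
class ScanConfig:
    width: int = 1000
    step: int = 10
    target_fraction: float = 0.05
    merge_bookended: bool = True
    #: windows with less than this fraction of their bases inside the
    #: analyzed space are never recruited (gap handling)
    min_analyzed_fraction: float = 0.5

    @property
    def n_steps(self) -> int:
        if self.width % self.step:
            raise ValidationError("width must be divisible by step")
        return self.width // self.step


@dataclass
class ChromosomeScan:
    """Densities of every sliding window on one chromosome.

    Window ``k`` spans ``[k*step, k*step + width)``; arrays are indexed
    by ``k``.
    """

    chrom: str
    step: int
    width: int
    d: np.ndarray  # weighted density per window
    raw: np.ndarray  # unweighted anchor count per window

    @property
    def n_windows(self) -> int:
        return len(self.d)

    def window(self, k: int) -> GenomicInterval:
        return GenomicInterval(self.chrom, k * self.step, k * self.step + self.width)


def step_counts(anchors: np.ndarray, extent: int, step: int = 10) -> np.ndarray:
    """Anchor count per 10-bp step over ``[0, extent)``."""
    n_steps = extent // step
    if len(anchors) == 0:
        return np.zeros(n_steps, dtype=np.int64)
    a = anchors[(anchors >= 0) & (anchors < n_steps * step)]
    return np.bincount(a // step, minlength=n_steps)[:n_steps]


def scan_chromosome(
    anchors: np.ndarray,
    chrom: str,
    extent: int,
    scheme: WeightScheme | None = None,
    config: ScanConfig | None = None,
) -> ChromosomeScan:
    """Weighted density of every full sliding window on a chromosome."""
    config = config or ScanConfig()
    scheme = scheme or build_weights(config.n_steps)
    counts = step_counts(np.asarray(anchors, dtype=np.int64), extent, config.step)
    if len(counts) < scheme.n_steps:
        return ChromosomeScan(chrom, config.step, config.width, np.zeros(0), np.zeros(0, dtype=np.int64))
    d = np.correlate(counts.astype(float), scheme.w, mode="valid") / scheme.total
    cs = np.concatenate([[0], np.cumsum(counts)])
    raw = cs[scheme.n_steps :] - cs[: len(counts) - scheme.n_steps + 1]
    return ChromosomeScan(chrom, config.step, config.width, d, raw.astype(np.int64))


@dataclass
class HotspotCall:
    """A merged region of recruited top-density windows for one kind."""

    region: GenomicInterval
    kind: str
    zone: str
    d_min_used: float
    n_windows_merged: int
    max_d: float = 0.0


# ---------------------------------------------------------------------------
# recruitment


def _greedy_recruit(
    order: np.ndarray,
    d: np.ndarray,
    entries_of: Callable[[int], np.ndarray],
    covered: np.ndarray,
    budget: float,
) -> list[int]:
    """Recruit ranked windows until unique covered entries would exceed budget.

    Windows tied at the same density are recruited all-or-none so the
    result does not depend on sort order within ties.
    """
    recruited: list[int] = []
    n_covered = int(covered.sum())
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and d[order[j]] == d[order[i]]:
            j += 1
        group = order[i:j]
        new_ids: list[np.ndarray] = []
        for idx in group:
            ids = entries_of(int(idx))
            new_ids.append(ids[~covered[ids]])
        new_unique = np.unique(np.concatenate(new_ids)) if new_ids else np.array([], dtype=np.int64)
        if n_covered + len(new_unique) > budget:
            break
        covered[new_unique] = True
        n_covered += len(new_unique)
        recruited.extend(int(x) for x in group)
        i = j
    return recruited


def recruit_top_windows(
    part1_d: np.ndarray,
    part1_entries: Sequence[np.ndarray],
    part2_d: np.ndarray,
    total_entries: int,
    target_fraction: float = 0.05,
) -> tuple[list[int], list[int], float | None]:
    """Zone-level recruitment on explicit per-window entry lists.

    ``part1_entries[i]`` lists the entry ids covered by Part I window
    ``i``.  Returns indices of recruited Part I and Part II windows and
    the recruitment threshold ``d_min`` (None if nothing was recruited).
    """
    if not (0 < target_fraction <= 1):
        raise ValidationError("target_fraction must be in (0, 1]")
    part1_d = np.asarray(part1_d, dtype=float)
    part2_d = np.asarray(part2_d, dtype=float)
    if total_entries == 0:
        warnings.warn("zone has zero entries of this kind; empty recruitment")
        return [], [], None
    all_ids = (
        np.concatenate([np.asarray(e) for e in part1_entries])
        if len(part1_entries)
        else np.array([], dtype=np.int64)
    )
    size = int(all_ids.max()) + 1 if len(all_ids) else 1
    covered = np.zeros(size, dtype=bool)
    order = np.argsort(-part1_d, kind="stable")
    rec1 = _greedy_recruit(
        order,
        part1_d,
        lambda i: np.asarray(part1_entries[i], dtype=np.int64),
        covered,
        target_fraction * total_entries,
    )
    if not rec1:
        return [], [], None
    d_min = float(part1_d[rec1].min())
    rec2 = [int(i) for i in np.flatnonzero(part2_d >= d_min)]
    return rec1, rec2, d_min


# ---------------------------------------------------------------------------
# genome-wide detection


def _mask_windows(
    intervals: list[GenomicInterval],
    n_windows: int,
    width: int,
    step: int,
) -> tuple[np.ndarray, np.ndarray]:
    """(fully-inside, overlapping) masks over the window grid."""
    full = np.zeros(n_windows, dtype=bool)
    over = np.zeros(n_windows, dtype=bool)
    for iv in intervals:
        k_lo = -(-iv.start // step)  # ceil
        k_hi = (iv.end - width) // step
        if k_hi >= 0 and k_lo <= k_hi:
            full[max(k_lo, 0) : min(k_hi, n_windows - 1) + 1] = True
        o_lo = (iv.start - width) // step + 1
        o_hi = -(-iv.end // step) - 1
        if o_hi >= 0 and o_lo <= o_hi:
            over[max(o_lo, 0) : min(o_hi, n_windows - 1) + 1] = True
    return full, over


def _window_coverage(
    intervals: list[GenomicInterval], extent: int, step: int, n_steps_win: int
) -> np.ndarray:
    """bp of ``intervals`` inside each sliding window (for gap handling)."""
    n_steps = extent // step
    cov = np.zeros(n_steps, dtype=float)
    for iv in intervals:
        s, e = iv.start, min(iv.end, n_steps * step)
        if e <= s:
            continue
        ks, ke = s // step, (e - 1) // step
        if ks == ke:
            cov[ks] += e - s
        else:
            cov[ks] += (ks + 1) * step - s
            cov[ke] += e - ke * step
            cov[ks + 1 : ke] += step
    cs = np.concatenate([[0], np.cumsum(cov)])
    n_win = n_steps - n_steps_win + 1
    if n_win <= 0:
        return np.zeros(0)
    return cs[n_steps_win:] - cs[:n_win]


def detect_hotspots(
    catalog: VariantCatalog,
    zones: ZonePartition,
    kind: str,
    config: ScanConfig | None = None,
) -> list[HotspotCall]:
    """Call density hotspots of one variant kind across the zoned genome."""
    config = config or ScanConfig()
    scheme = build_weights(config.n_steps)
    chroms = zones.chromosomes

    # anchors with globally unique entry ids
    pos_by_chrom: dict[str, np.ndarray] = {}
    eid_by_chrom: dict[str, np.ndarray] = {}
    offset = 0
    for chrom in chroms:
        sub = catalog.subset_kind(kind)
        sub = sub[sub["chrom"] == chrom]
        pos, eid = kind_anchors(sub, kind)
        pos_by_chrom[chrom] = pos
        eid_by_chrom[chrom] = eid + offset
        offset += len(sub)
    total_entries_all = offset

    scans = {
        chrom: scan_chromosome(
            pos_by_chrom[chrom], chrom, zones.chrom_extent(chrom), scheme, config
        )
        for chrom in chroms
    }
    analyzed = zones.analyzed_space
    eligible = {}
    for chrom in chroms:
        n_win = scans[chrom].n_windows
        cov = _window_coverage(
            [iv for iv in analyzed if iv.chrom == chrom],
            zones.chrom_extent(chrom),
            config.step,
            config.n_steps,
        )
        eligible[chrom] = cov[:n_win] >= config.min_analyzed_fraction * config.width

    covered = np.zeros(max(total_entries_all, 1), dtype=bool)
    # recruited window -> (zone label of first recruitment, d_min of that zone)
    recruited: dict[str, dict[int, tuple[str, float]]] = {c: {} for c in chroms}

    for label in ZONE_LABELS:
        union = zones.zone_union(label)
        # entries of the kind whose anchors fall inside this zone type
        in_zone_ids: list[np.ndarray] = []
        for chrom in chroms:
            ivs = [iv for iv in union if iv.chrom == chrom]
            if not ivs:
                continue
            pos = pos_by_chrom[chrom]
            starts = np.array([iv.start for iv in ivs])
            ends = np.array([iv.end for iv in ivs])
            j = np.searchsorted(starts, pos, side="right") - 1
            ok = j >= 0
            ok[ok] &= pos[ok] < ends[j[ok]]
            in_zone_ids.append(eid_by_chrom[chrom][ok])
        total_zone = len(np.unique(np.concatenate(in_zone_ids))) if in_zone_ids else 0
        if total_zone == 0:
            warnings.warn(f"{kind}: no entries in {label} zones; skipping")
            continue

        p1_chrom, p1_k, p1_d = [], [], []
        p2_chrom, p2_k, p2_d = [], [], []
        for chrom in chroms:
            scan = scans[chrom]
            if scan.n_windows == 0:
                continue
            ivs = [iv for iv in union if iv.chrom == chrom]
            full, over = _mask_windows(ivs, scan.n_windows, config.width, config.step)
            part1 = full & eligible[chrom]
            part2 = over & ~full & eligible[chrom]
            for store_c, store_k, store_d, mask in (
                (p1_chrom, p1_k, p1_d, part1),
                (p2_chrom, p2_k, p2_d, part2),
            ):
                ks = np.flatnonzero(mask)
                store_c.extend([chrom] * len(ks))
                store_k.append(ks)
                store_d.append(scan.d[ks])

        p1_k = np.concatenate(p1_k) if p1_k else np.array([], dtype=int)
        p1_d = np.concatenate(p1_d) if p1_d else np.array([])
        p2_k = np.concatenate(p2_k) if p2_k else np.array([], dtype=int)
        p2_d = np.concatenate(p2_d) if p2_d else np.array([])

        def entries_of(i: int) -> np.ndarray:
            chrom = p1_chrom[i]
            s = p1_k[i] * config.step
            pos = pos_by_chrom[chrom]
            lo, hi = np.searchsorted(pos, [s, s + config.width])
            return eid_by_chrom[chrom][lo:hi]

        zone_covered = covered.copy()
        zone_covered[:] = False
        order = np.argsort(-p1_d, kind="stable")
        rec1 = _greedy_recruit(
            order, p1_d, entries_of, zone_covered, config.target_fraction * total_zone
        )
        if not rec1:
            continue
        d_min = float(p1_d[rec1].min())
        for i in rec1:
            recruited[p1_chrom[i]].setdefault(int(p1_k[i]), (label, d_min))
        for i in np.flatnonzero(p2_d >= d_min):
            recruited[p2_chrom[i]].setdefault(int(p2_k[i]), (label, d_min))

    # merge per chromosome into maximal hotspot regions
    calls: list[HotspotCall] = []
    for chrom in chroms:
        if not recruited[chrom]:
            continue
        scan = scans[chrom]
        ks = np.array(sorted(recruited[chrom]))
        run_start = 0
        for idx in range(1, len(ks) + 1):
            end_prev = ks[idx - 1] * config.step + config.width
            joined = idx < len(ks) and (
                ks[idx] * config.step < end_prev
                or (config.merge_bookended and ks[idx] * config.step == end_prev)
            )
            if not joined:
                group = ks[run_start:idx]
                best = group[int(np.argmax(scan.d[group]))]
                label, d_min = recruited[chrom][int(best)]
                calls.append(
                    HotspotCall(
                        region=GenomicInterval(
                            chrom,
                            int(group[0]) * config.step,
                            int(group[-1]) * config.step + config.width,
                        ),
                        kind=kind,
                        zone=label,
                        d_min_used=d_min,
                        n_windows_merged=len(group),
                        max_d=float(scan.d[group].max()),
                    )
                )
                run_start = idx
    return calls
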