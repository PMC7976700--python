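"""Genomic coordinate conventions and interval algebra.

All coordinates are 0-based half-open internally.  Conversion to the
1-based closed convention used in tabular report files, or to BED,
happens only at I/O time (:mod:`gvhotspots.io`).  Chromosome names are
opaque strings: no ``chr`` prefix normalisation is applied implicitly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

ZONE_LABELS = ("Genic", "Proximal", "Distal")


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if self.start < 0:
            raise ValidationError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


def merge_intervals(
    intervals: Iterable[GenomicInterval], merge_bookended: bool = False
) -> list[GenomicInterval]:
    """Merge intervals into a sorted, pairwise-disjoint set.

    The base-pair union is preserved.  With ``merge_bookended`` intervals
    that touch (``end_a == start_b``) are joined as well.
    """
    ivs = sorted(intervals)
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and iv.chrom == out[-1].chrom:
            prev = out[-1]
            joined = iv.start < prev.end or (merge_bookended and iv.start == prev.end)
            if joined:
                if iv.end > prev.end:
                    out[-1] = GenomicInterval(prev.chrom, prev.start, iv.end)
                continue
        out.append(iv)
    return out


def intersect_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of base pairs shared by two intervals (0 across chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def union_length(intervals: Iterable[GenomicInterval]) -> int:
    """Total distinct base pairs covered by a set of intervals."""
    return sum(iv.length for iv in merge_intervals(intervals))


def subtract_intervals(
    base: Iterable[GenomicInterval], remove: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Base-pair set difference ``base \\ remove`` as disjoint intervals."""
    base_m = merge_intervals(base)
    rem_m = merge_intervals(remove)
    out: list[GenomicInterval] = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for r in rem_m:
        by_chrom.setdefault(r.chrom, []).append(r)
    for b in base_m:
        cur = b.start
        for r in by_chrom.get(b.chrom, []):
            if r.end <= cur or r.start >= b.end:
                continue
            if r.start > cur:
                out.append(GenomicInterval(b.chrom, cur, r.start))
            cur = max(cur, r.end)
            if cur >= b.end:
                break
        if cur < b.end:
            out.append(GenomicInterval(b.chrom, cur, b.end))
    return out


def intersect_sets(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Base-pair intersection of two interval sets, as disjoint intervals."""
    a_m = merge_intervals(a)
    b_m = merge_intervals(b)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in b_m:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out = []
    for iv in a_m:
        for other in by_chrom.get(iv.chrom, []):
            s, e = max(iv.start, other.start), min(iv.end, other.end)
            if e > s:
                out.append(GenomicInterval(iv.chrom, s, e))
    return sorted(out)


def tile_windows(region: GenomicInterval, width: int, step: int) -> list[GenomicInterval]:
    """Tile ``region`` with windows of ``width`` advancing by ``step``.

    Windows extending past ``region.end`` are dropped, so the count is
    ``floor((L - width)/step) + 1`` for region length ``L >= width``.
    """
    if width <= 0 or step <= 0:
        raise ValidationError("width and step must be positive")
    if width < step:
        raise ValidationError("width must be >= step")
    if width % step != 0:
        raise ValidationError("width must be divisible by step")
    out = []
    start = region.start
    while start + width <= region.end:
        out.append(GenomicInterval(region.chrom, start, start + width))
        start += step
    return out


@dataclass
class GapTrack:
    """Assembly gap intervals; normalised to a disjoint sorted set."""

    gaps: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gaps = merge_intervals(self.gaps, merge_bookended=True)


@dataclass
class ZonePartition:
    """500-kb zone windows labelled Genic/Proximal/Distal, plus gaps.

    ``analyzed_space`` is the union of zone windows minus gap intervals;
    it is the universe within which densities, hotspots and Monte Carlo
    shuffles are defined.
    """

    windows: list[tuple[GenomicInterval, str]]
    gaps: GapTrack = field(default_factory=GapTrack)

    def __post_init__(self) -> None:
        seen: list[GenomicInterval] = []
        for iv, label in self.windows:
            if label not in ZONE_LABELS:
                raise ValidationError(f"unknown zone label {label!r}")
            seen.append(iv)
        merged = merge_intervals(seen)
        if sum(m.length for m in merged) != sum(iv.length for iv in seen):
            raise ValidationError("zone windows overlap")

    def zone_union(self, label: str) -> list[GenomicInterval]:
        """Merged union of all windows carrying ``label``."""
        if label not in ZONE_LABELS:
            raise ValidationError(f"unknown zone label {label!r}")
        return merge_intervals(
            [iv for iv, lab in self.windows if lab == label], merge_bookended=True
        )

    @property
    def analyzed_space(self) -> list[GenomicInterval]:
        return subtract_intervals([iv for iv, _ in self.windows], self.gaps.gaps)

    @property
    def chromosomes(self) -> list[str]:
        return sorted({iv.chrom for iv, _ in self.windows})

    def chrom_extent(self, chrom: str) -> int:
        """Rightmost covered coordinate on ``chrom`` (scan upper bound)."""
        ends = [iv.end for iv, _ in self.windows if iv.chrom == chrom]
        if not ends:
            raise ValidationError(f"no zone windows on {chrom}")
        return max(ends)
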