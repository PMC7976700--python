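"""Readers and writers for the plain-text formats used by the pipeline.

Internally everything is 0-based half-open.  BED files stay in the BED
dialect (0-based half-open); tabular report files are written in the
1-based closed convention (``start + 1``, ``end`` unchanged).
"""
from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd

from .intervals import GapTrack, GenomicInterval, ValidationError, ZonePartition


def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read BED3+ (extra columns ignored) into intervals."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
            except (ValueError, ValidationError) as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            out.append(iv)
    return sorted(out)


def write_bed(
    path: str | os.PathLike,
    intervals: Iterable[GenomicInterval],
    names: Sequence[str] | None = None,
) -> None:
    intervals = list(intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            row = [iv.chrom, str(iv.start), str(iv.end)]
            if names is not None:
                row.append(str(names[i]))
            fh.write("\t".join(row) + "\n")


def read_zones_bed(path: str | os.PathLike, gaps_path: str | os.PathLike | None = None) -> ZonePartition:
    """Read a BED4 of labelled 500-kb zone windows (name = zone label)."""
    windows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValidationError(f"{path}:{lineno}: zone BED needs 4 columns")
            windows.append(
                (GenomicInterval(parts[0], int(parts[1]), int(parts[2])), parts[3])
            )
    gaps = GapTrack(read_bed(gaps_path)) if gaps_path else GapTrack()
    return ZonePartition(windows=windows, gaps=gaps)


def write_zones_bed(path: str | os.PathLike, zones: ZonePartition) -> None:
    with open(path, "w") as fh:
        for iv, label in zones.windows:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}\n")


def intervals_to_frame_1based(intervals: Iterable[GenomicInterval]) -> pd.DataFrame:
    """Intervals as a 1-based closed (chrom, start, end) table."""
    rows = [(iv.chrom, iv.start + 1, iv.end) for iv in intervals]
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def frame_1based_to_intervals(df: pd.DataFrame) -> list[GenomicInterval]:
    return [
        GenomicInterval(r.chrom, int(r.start) - 1, int(r.end))
        for r in df.itertuples(index=False)
    ]


def write_tsv(path: str | os.PathLike, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
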