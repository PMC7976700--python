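"""Consensus replication phase per 1-kb window and phase segments.

Each of 15 cell lines scores every window in six replication phases
(G1b, S1, S2, S3, S4, G2).  Per cell line the highest-scoring phase(s)
vote (within-line ties each cast a vote); the window's representative
phase is the unique modal phase across cell lines.  Windows assessed in
fewer than nine cell lines ("more than eight of fifteen"), or whose
modal phase is tied, are excluded.  Runs of successive windows sharing
a representative phase merge into phase segments.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, ValidationError

PHASES = ("G1b", "S1", "S2", "S3", "S4", "G2")


@dataclass
class PhaseCall:
    phase: str | None
    reason: str | None = None  # set when excluded

    @property
    def excluded(self) -> bool:
        return self.phase is None


@dataclass
class PhaseSegment:
    region: GenomicInterval
    phase: str
    n_windows: int


def representative_phase(
    scores: Mapping[str, Mapping[str, float]],
    min_cell_lines: int = 9,
) -> PhaseCall:
    """Consensus phase for one window from per-cell-line phase scores.

    ``scores[cell_line][phase]``; a cell line missing from the mapping
    (or with no scores) has no data.  Ties on input scores are exact
    equality — scores are tabulated values, not continuous measurements.
    """
    votes = {p: 0 for p in PHASES}
    n_lines = 0
    for line_scores in scores.values():
        vals = {p: line_scores[p] for p in PHASES if p in line_scores and line_scores[p] is not None}
        if not vals:
            continue
        n_lines += 1
        top = max(vals.values())
        for p, v in vals.items():
            if v == top:
                votes[p] += 1
    if n_lines < min_cell_lines:
        return PhaseCall(None, "insufficient cell lines")
    best = max(votes.values())
    modal = [p for p in PHASES if votes[p] == best]
    if len(modal) > 1:
        return PhaseCall(None, "tied representative")
    return PhaseCall(modal[0])


def consensus_phases(
    tables: Mapping[str, pd.DataFrame],
    min_cell_lines: int = 9,
) -> pd.DataFrame:
    """Vectorised consensus over per-cell-line score tables.

    Each table has columns ``chrom, start`` plus the six phase columns,
    one row per 1-kb window on a shared tiling; NaN rows mean the cell
    line did not assess that window.  Returns the tiling with a
    ``phase`` column (None where excluded) and a ``reason`` column.
    """
    lines = list(tables)
    if not lines:
        raise ValidationError("no cell-line tables supplied")
    ref = tables[lines[0]][["chrom", "start"]].reset_index(drop=True)
    n = len(ref)
    votes = np.zeros((n, len(PHASES)), dtype=np.int32)
    n_lines = np.zeros(n, dtype=np.int32)
    for line in lines:
        t = tables[line].reset_index(drop=True)
        if len(t) != n or not (t["start"].to_numpy() == ref["start"].to_numpy()).all():
            raise ValidationError(f"cell line {line}: window tiling mismatch")
        sc = t[list(PHASES)].to_numpy(dtype=float)
        has = ~np.isnan(sc).any(axis=1)
        n_lines += has.astype(np.int32)
        top = np.nanmax(np.where(has[:, None], sc, -np.inf), axis=1)
        votes += (has[:, None]) & (sc == top[:, None])
    best = votes.max(axis=1)
    n_modal = (votes == best[:, None]).sum(axis=1)
    phase_idx = votes.argmax(axis=1)

    out = ref.copy()
    out["end"] = out["start"] + 1000
    phase = np.array([PHASES[i] for i in phase_idx], dtype=object)
    reason = np.array([None] * n, dtype=object)
    excl_lines = n_lines < min_cell_lines
    excl_tie = (~excl_lines) & (n_modal > 1)
    phase[excl_lines | excl_tie] = None
    reason[excl_lines] = "insufficient cell lines"
    reason[excl_tie] = "tied representative"
    out["phase"] = phase
    out["reason"] = reason
    return out


def phase_segments(assignments: pd.DataFrame) -> list[PhaseSegment]:
    """Merge successive same-phase windows; excluded windows break runs.

    ``assignments`` as returned by :func:`consensus_phases` (columns
    chrom, start, end, phase), sorted by (chrom, start).
    """
    segs: list[PhaseSegment] = []
    cur: dict | None = None
    a = assignments.sort_values(["chrom", "start"])
    for row in a.itertuples(index=False):
        if row.phase is None:
            if cur:
                segs.append(PhaseSegment(**cur))
                cur = None
            continue
        contiguous = (
            cur is not None
            and cur["region"].chrom == row.chrom
            and cur["region"].end == row.start
            and cur["phase"] == row.phase
        )
        if contiguous:
            cur["region"] = GenomicInterval(row.chrom, cur["region"].start, int(row.end))
            cur["n_windows"] += 1
        else:
            if cur:
                segs.append(PhaseSegment(**cur))
            cur = {
                "region": GenomicInterval(row.chrom, int(row.start), int(row.end)),
                "phase": row.phase,
                "n_windows": 1,
            }
    if cur:
        segs.append(PhaseSegment(**cur))
    return segs
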