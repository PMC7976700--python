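"""Consensus replication phase per 1-kb window and merged phase segments.

Fifteen pseudo cell lines score every window in six phases (G1b..G2);
per line the top-scoring phase votes, the unique modal phase wins, and
windows assessed in fewer than nine lines are excluded.
"""
from collections import Counter

from gvhotspots import SimConfig, consensus_phases, phase_segments, simulate_bundle

bundle = simulate_bundle(SimConfig(seed=4))
assignments = consensus_phases(bundle.repliseq)
segments = phase_segments(assignments)

n_assigned = int(assignments["phase"].notna().sum())
print(f"{n_assigned} of {len(assignments)} windows received a consensus phase")
print("exclusions:", dict(Counter(r for r in assignments['reason'] if r)))
by_phase = Counter(s.phase for s in segments)
print(f"{len(segments)} phase segments:", dict(by_phase))
longest = max(segments, key=lambda s: s.region.length)
print(f"longest segment: {longest.region} ({longest.phase}, "
      f"{longest.n_windows} windows)")
print(
    "\nSegments are maximal runs of adjacent windows sharing the same\n"
    "representative phase; excluded windows break runs."
)
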