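"""CNV size classification and hotspot clusters.

Fits the four-class size cuts from a simulated CNV length mixture,
then scans three variant kinds on the default 2 x 5 Mb bundle and
merges overlapping hotspots of distinct kinds into clusters.
"""
import numpy as np

from gvhotspots import SimConfig, call_clusters, composition_summary, detect_hotspots, simulate_bundle
from gvhotspots.catalog import fit_size_bounds
from gvhotspots.simulate import CnvMixture, simulate_cnv_lengths

rng = np.random.default_rng(1)
lengths, _ = simulate_cnv_lengths(20_000, CnvMixture(), rng)
bounds = fit_size_bounds(lengths)
print(
    f"fitted size-class cuts: {bounds.cut1} / {bounds.cut2} / {bounds.cut3} bp\n"
    "(valleys of the four-peak log-length distribution; the standard\n"
    " germline cuts are 61 / 952 / 15,571 bp)\n"
)

bundle = simulate_bundle(SimConfig(seed=1))
hotspots = {
    kind: detect_hotspots(bundle.catalog, bundle.zones, kind)
    for kind in ("SNP", "SID", "MCNV")
}
clusters = call_clusters(hotspots)
print(f"hotspots per kind: { {k: len(v) for k, v in hotspots.items()} }")
print(f"{len(clusters)} clusters of >= 2 distinct kinds:")
print(composition_summary(clusters).to_string(index=False))
print(
    "\nA cluster is the merged region of overlapping hotspots of different\n"
    "kinds; the composition label lists the member kinds."
)
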