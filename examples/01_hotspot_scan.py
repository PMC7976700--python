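"""Detect density hotspots of one variant kind on a small synthetic genome.

Builds a 1 x 2 Mb genome with one planted SNP-dense region per zone
type, runs the weighted sliding-window scan, and compares the calls
with the planted truth.
"""
from gvhotspots import SimConfig, detect_hotspots, simulate_bundle

config = SimConfig(
    seed=1,
    n_chroms=1,
    chrom_length=2_000_000,
    gv_plants={"SNP": (10.0, (1, 1, 0))},
    plant_taper=1000,
    possel_runs_per_metric=5,
    negsel_runs=3,
    n_genes=20,
)
bundle = simulate_bundle(config)

calls = detect_hotspots(bundle.catalog, bundle.zones, "SNP")

print(f"{len(bundle.truth.gv_hotspots['SNP'])} planted SNP hotspots:")
for iv in bundle.truth.gv_hotspots["SNP"]:
    print(f"  truth  {iv}  ({iv.length} bp)")
print(f"{len(calls)} hotspot calls:")
for c in calls:
    print(
        f"  call   {c.region}  zone={c.zone}  D_min={c.d_min_used:.3f}  "
        f"windows={c.n_windows_merged}"
    )
print(
    "\nEach call is a merged run of 1-kb sliding windows whose weighted\n"
    "density ranked in the top 5% coverage of SNP entries in its zone;\n"
    "D_min is the lowest recruited density, the zone's detection threshold.\n"
    "No hotspot was planted in the Distal zone, so its 5% budget lands on\n"
    "background density fluctuations — note their far lower D_min."
)
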