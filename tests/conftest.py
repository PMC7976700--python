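import warnings

import numpy as np
import pytest

from gvhotspots import SimConfig, simulate_bundle
from gvhotspots.intervals import GenomicInterval
from gvhotspots.simulate import SyntheticBundle

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def bundle() -> SyntheticBundle:
    """Default-condition synthetic bundle shared by recovery tests."""
    return simulate_bundle(SimConfig(seed=11))


@pytest.fixture(scope="session")
def small_bundle() -> SyntheticBundle:
    """A 1 x 2 Mb bundle for fast pipeline tests."""
    cfg = SimConfig(
        seed=5,
        n_chroms=1,
        chrom_length=2_000_000,
        gv_plants={"SNP": (10.0, (1, 1, 0))},
        plant_taper=1000,
        possel_runs_per_metric=10,
        negsel_runs=5,
        n_genes=20,
        n_recurrent_sites=5,
    )
    return simulate_bundle(cfg)


def jaccard(a: GenomicInterval, b: GenomicInterval) -> float:
    if a.chrom != b.chrom:
        return 0.0
    inter = max(0, min(a.end, b.end) - max(a.start, b.start))
    union = a.length + b.length - inter
    return inter / union


def mask_of(intervals, chrom: str, size: int) -> np.ndarray:
    """Per-base boolean oracle for interval algebra on a toy chromosome."""
    m = np.zeros(size, dtype=bool)
    for iv in intervals:
        if iv.chrom == chrom:
            m[iv.start : iv.end] = True
    return m
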