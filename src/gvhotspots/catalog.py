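"""Variant catalogs: input parsing, CNV size classes, anchor positions.

Variant kinds
-------------
``SNP``  biallelic single-nucleotide polymorphism
``SID``  small indel
``MST``  microsatellite
``CNV``  germline copy-number variant (classified into SCNV/MCNV/LCNV/ECNV)
``SDP``  segmental duplication
``CNVT`` somatic tumour copy-number variant (counted by breakpoints)

For density scanning, short variants (SNP, SID, MST, SCNV, MCNV) are
anchored at their start position; long variants (LCNV, ECNV, SDP, CNVT)
contribute one anchor per breakpoint (start and end-1).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .intervals import GenomicInterval, ValidationError

VARIANT_KINDS = ("SNP", "SID", "MST", "CNV", "SDP", "CNVT")
SIZE_CLASSES = ("SCNV", "MCNV", "LCNV", "ECNV")
#: kinds a hotspot scan can run on (CNVs are scanned per size class)
SCAN_KINDS = ("SNP", "SID", "MST", "SCNV", "MCNV", "LCNV", "ECNV", "SDP")
SHORT_KINDS = frozenset({"SNP", "SID", "MST", "SCNV", "MCNV"})
LONG_KINDS = frozenset({"LCNV", "ECNV", "SDP", "CNVT"})


@dataclass(frozen=True)
class SizeClassBounds:
    """Cut points separating the four CNV size classes.

    Classes are half-open on the left and closed on the right:
    SCNV (min_len, cut1], MCNV (cut1, cut2], LCNV (cut2, cut3],
    ECNV (cut3, inf).  Defaults are the standard cuts 61 / 952 / 15,571 bp
    with a 5-bp lower bound.
    """

    cut1: int = 61
    cut2: int = 952
    cut3: int = 15_571
    min_len: int = 5

    def __post_init__(self) -> None:
        if not (self.min_len < self.cut1 < self.cut2 < self.cut3):
            raise ValidationError("size-class cuts must satisfy min_len<cut1<cut2<cut3")


def classify_cnv(length: int, bounds: SizeClassBounds | None = None) -> str:
    """Assign a CNV length to SCNV/MCNV/LCNV/ECNV."""
    bounds = bounds or SizeClassBounds()
    if length <= bounds.min_len:
        raise ValidationError(
            f"length {length} is below the {bounds.min_len}-bp minimum"
        )
    if length <= bounds.cut1:
        return "SCNV"
    if length <= bounds.cut2:
        return "MCNV"
    if length <= bounds.cut3:
        return "LCNV"
    return "ECNV"


@dataclass
class VariantRecord:
    """One germline or somatic variant entry."""

    kind: str
    interval: GenomicInterval
    maf: float | None = None
    daf_by_pop: Mapping[str, float] | None = None
    size_class: str | None = None
    sample: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in VARIANT_KINDS:
            raise ValidationError(f"unknown variant kind {self.kind!r}")
        if self.maf is not None and not (0.0 <= self.maf <= 0.5):
            raise ValidationError(f"maf {self.maf} outside [0, 0.5]")
        if self.daf_by_pop:
            for pop, daf in self.daf_by_pop.items():
                if not (0.0 <= daf <= 1.0):
                    raise ValidationError(f"DAF {daf} for {pop} outside [0, 1]")
        if self.size_class is not None and self.size_class not in SIZE_CLASSES:
            raise ValidationError(f"unknown size class {self.size_class!r}")

    @property
    def length(self) -> int:
        return self.interval.length


class VariantCatalog:
    """A sorted collection of variants of mixed kinds.

    Backed by a DataFrame with columns
    ``chrom, start, end, kind, maf, size_class, sample`` sorted by
    (chrom, start).  ``records`` materialises :class:`VariantRecord`
    objects on demand; heavy operations work on the frame directly.
    """

    COLUMNS = ["chrom", "start", "end", "kind", "maf", "size_class", "sample"]

    def __init__(self, df: pd.DataFrame, provenance: str = ""):
        for col in self.COLUMNS:
            if col not in df.columns:
                df = df.assign(**{col: None})
        if (df["end"] <= df["start"]).any():
            bad = df.index[(df["end"] <= df["start"])][0]
            raise ValidationError(f"record {bad}: end <= start")
        self.df = (
            df[self.COLUMNS]
            .sort_values(["chrom", "start", "end"], kind="stable")
            .reset_index(drop=True)
        )
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_records(
        cls, records: Iterable[VariantRecord], provenance: str = ""
    ) -> "VariantCatalog":
        rows = [
            (
                r.interval.chrom,
                r.interval.start,
                r.interval.end,
                r.kind,
                r.maf,
                r.size_class,
                r.sample,
            )
            for r in records
        ]
        return cls(pd.DataFrame(rows, columns=cls.COLUMNS), provenance)

    @property
    def records(self) -> list[VariantRecord]:
        out = []
        for r in self.df.itertuples(index=False):
            out.append(
                VariantRecord(
                    kind=r.kind,
                    interval=GenomicInterval(r.chrom, int(r.start), int(r.end)),
                    maf=None if pd.isna(r.maf) else float(r.maf),
                    size_class=None if pd.isna(r.size_class) else r.size_class,
                    sample=None if pd.isna(r.sample) else r.sample,
                )
            )
        return out

    def subset_kind(self, kind: str) -> pd.DataFrame:
        """Rows of one scan kind (size classes select classified CNVs)."""
        if kind in SIZE_CLASSES:
            return self.df[(self.df["kind"] == "CNV") & (self.df["size_class"] == kind)]
        return self.df[self.df["kind"] == kind]

    def with_size_classes(self, bounds: SizeClassBounds | None = None) -> "VariantCatalog":
        """Return a copy in which every CNV/CNVT row carries its size class."""
        bounds = bounds or SizeClassBounds()
        df = self.df.copy()
        mask = df["kind"].isin(["CNV", "CNVT"])
        lengths = (df.loc[mask, "end"] - df.loc[mask, "start"]).to_numpy()
        df.loc[mask, "size_class"] = [classify_cnv(int(l), bounds) for l in lengths]
        return VariantCatalog(df, self.provenance)


def read_variant_table(
    path: str,
    format: str,
    kind: str,
    vcf_pop_af_fields: Mapping[str, str] | None = None,
) -> VariantCatalog:
    """Read variants from VCF, BED or TSV into a catalog.

    VCF is restricted to biallelic records; coordinates are converted to
    the internal 0-based half-open convention.  ``vcf_pop_af_fields``
    maps population name -> INFO field carrying its allele frequency.
    """
    if kind not in VARIANT_KINDS:
        raise ValidationError(f"unknown variant kind {kind!r}")
    if format == "vcf":
        return _read_vcf(path, kind, vcf_pop_af_fields or {})
    if format == "bed":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValidationError(f"{path}:{lineno}: expected >=3 columns")
                start, end = int(parts[1]), int(parts[2])
                if end <= start:
                    raise ValidationError(f"{path}:{lineno}: end <= start")
                rows.append((parts[0], start, end, kind, None, None, None))
        return VariantCatalog(
            pd.DataFrame(rows, columns=VariantCatalog.COLUMNS), provenance=str(path)
        )
    if format == "tsv":
        df = pd.read_csv(path, sep="\t")
        required = {"chrom", "start", "end"}
        if not required.issubset(df.columns):
            raise ValidationError(f"{path}: TSV needs columns {sorted(required)}")
        bad = df.index[df["end"] < df["start"]]
        if len(bad):
            raise ValidationError(f"{path}: line {bad[0] + 2}: end < start")
        out = pd.DataFrame(
            {
                "chrom": df["chrom"].astype(str),
                # tabular inputs are 1-based closed
                "start": df["start"].astype(int) - 1,
                "end": df["end"].astype(int),
                "kind": kind,
                "maf": df.get("maf"),
                "size_class": df.get("size_class"),
                "sample": df.get("sample"),
            }
        )
        return VariantCatalog(out, provenance=str(path))
    raise ValidationError(f"unknown format {format!r}")


def _read_vcf(path: str, kind: str, pop_af_fields: Mapping[str, str]) -> VariantCatalog:
    from cyvcf2 import VCF

    rows = []
    for var in VCF(str(path)):
        if len(var.ALT) != 1:  # biallelic sites only
            continue
        start = var.start  # 0-based
        end = var.end
        af = var.INFO.get("AF")
        maf = None
        if af is not None:
            af = float(af[0] if isinstance(af, tuple) else af)
            maf = min(af, 1.0 - af)
        rows.append((var.CHROM, start, max(end, start + 1), kind, maf, None, None))
    return VariantCatalog(
        pd.DataFrame(rows, columns=VariantCatalog.COLUMNS), provenance=str(path)
    )


def filter_rare_exonic_snps(
    catalog: VariantCatalog,
    exome_targets: Sequence[GenomicInterval],
    maf_cut: float = 0.01,
) -> VariantCatalog:
    """Drop SNPs with MAF below ``maf_cut`` that fall inside exome targets.

    Rare alleles are over-discovered inside exome pull-down target
    boundaries, so only target-resident rare SNPs are removed; everything
    else is kept.  A target-resident SNP without a MAF is an error, since
    the filter cannot be applied to it.
    """
    if not exome_targets:
        return catalog
    df = catalog.df
    snp = df["kind"] == "SNP"
    targets = sorted(exome_targets)
    starts = np.array([t.start for t in targets])
    ends = np.array([t.end for t in targets])
    chroms = np.array([t.chrom for t in targets])

    inside = np.zeros(len(df), dtype=bool)
    for chrom in np.unique(df.loc[snp, "chrom"]):
        sel = snp & (df["chrom"] == chrom)
        tmask = chroms == chrom
        if not tmask.any():
            continue
        pos = df.loc[sel, "start"].to_numpy()
        idx = np.searchsorted(starts[tmask], pos, side="right") - 1
        ok = idx >= 0
        ok[ok] &= pos[ok] < ends[tmask][idx[ok]]
        inside[np.flatnonzero(sel)] = ok
    if (inside & df["maf"].isna().to_numpy()).any():
        raise ValidationError("SNP inside exome target lacks MAF; cannot filter")
    drop = inside & (df["maf"].to_numpy() < maf_cut)
    return VariantCatalog(df[~drop].copy(), catalog.provenance)


@dataclass
class CutpointConfig:
    """Settings for valley detection on the log10 length distribution."""

    bandwidth: float = 0.08  # log10 units, Gaussian KDE
    peak_min_frac: float = 0.02  # peaks below this fraction of max ignored
    poly_degree: int = 4
    grid_points: int = 1024


def cnv_size_cutpoints(
    lengths: Sequence[int] | np.ndarray, config: CutpointConfig | None = None
) -> list[int]:
    """Derive size-class cut points from a CNV length distribution.

    A Gaussian KDE of log10(length) is scanned for local maxima; between
    each successive peak pair a polynomial is fitted to the density and
    its interior minimum becomes a cut.  Returns one cut per valley,
    strictly increasing; a four-mode distribution yields the three cuts
    of the standard scheme (see :func:`fit_size_bounds`).
    """
    config = config or CutpointConfig()
    x = np.log10(np.asarray(lengths, dtype=float))
    if len(x) < 10:
        raise ValidationError("need at least 10 lengths")
    kde = gaussian_kde(x, bw_method=config.bandwidth / max(x.std(), 1e-9))
    grid = np.linspace(x.min() - 0.2, x.max() + 0.2, config.grid_points)
    dens = kde(grid)

    peaks = [
        i
        for i in range(1, len(grid) - 1)
        if dens[i] > dens[i - 1]
        and dens[i] >= dens[i + 1]
        and dens[i] >= config.peak_min_frac * dens.max()
    ]
    if len(peaks) < 2:
        raise ValidationError("fewer than 2 peaks in the length distribution")

    cuts = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        seg_x, seg_y = grid[a : b + 1], dens[a : b + 1]
        deg = min(config.poly_degree, len(seg_x) - 1)
        coef = np.polyfit(seg_x, seg_y, deg)
        fine = np.linspace(seg_x[0], seg_x[-1], 2048)
        fit = np.polyval(coef, fine)
        interior = slice(1, -1)
        j = int(np.argmin(fit[interior])) + 1
        if j <= 1 or j >= len(fine) - 2:
            raise ValidationError("no interior minimum between peaks")
        cuts.append(10 ** fine[j])

    return sorted(int(round(c)) for c in cuts)


def fit_size_bounds(
    lengths: Sequence[int] | np.ndarray, config: CutpointConfig | None = None
) -> SizeClassBounds:
    """Fit the standard four-class bounds from a four-mode length sample."""
    cuts = cnv_size_cutpoints(lengths, config)
    if len(cuts) != 3:
        raise ValidationError(
            f"expected 3 cuts for the four-class scheme, found {len(cuts)}"
        )
    return SizeClassBounds(cut1=cuts[0], cut2=cuts[1], cut3=cuts[2])


def anchor_positions(record: VariantRecord, convention: str = "default") -> list[int]:
    """Genome positions at which a variant is counted in the density scan.

    Short kinds contribute a single anchor at their start; long kinds one
    anchor per breakpoint (start and end-1, internally 0-based).
    """
    if convention != "default":
        raise ValidationError(f"unknown counting convention {convention!r}")
    kind = record.size_class if record.kind in ("CNV", "CNVT") and record.size_class else record.kind
    if kind == "CNVT":
        kind = "CNVT"
    if kind in SHORT_KINDS:
        return [record.interval.start]
    if kind in LONG_KINDS or kind == "CNVT":
        if record.interval.length == 1:
            return [record.interval.start]
        return [record.interval.start, record.interval.end - 1]
    # unclassified CNV: fall back to breakpoints
    return [record.interval.start, record.interval.end - 1]


def kind_anchors(df: pd.DataFrame, kind: str) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised anchors for one scan kind.

    Returns ``(positions, entry_ids)`` where two breakpoints of the same
    entry share an id, so unique-entry accounting never double-counts.
    """
    starts = df["start"].to_numpy(dtype=np.int64)
    ends = df["end"].to_numpy(dtype=np.int64)
    ids = np.arange(len(df), dtype=np.int64)
    if kind in SHORT_KINDS:
        return starts, ids
    pos = np.concatenate([starts, ends - 1])
    eid = np.concatenate([ids, ids])
    order = np.argsort(pos, kind="stable")
    return pos[order], eid[order]
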