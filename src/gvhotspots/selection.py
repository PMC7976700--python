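"""Selection scans on a fixed 1-kb window tiling.

Positive selection is measured per window by (i) the mean derived-allele
frequency (DAF) of its SNPs, (ii) the mean over SNPs of the maximum
|DAF difference| across population pairs (|dDAF|), and (iii) the mean
haplotype statistic |nSL|.  Purifying selection by (i) mean phyloP
conservation and (ii) nucleotide diversity pi.  Windows in the top 5%
(bottom 5% for pi) of a metric are earmarked and each candidate is then
compared with 10,000 windows resampled from its own decile of
informative-site counts — matching absorbs the higher sampling variance
of site-based means in sparse windows.  Candidates with empirical
p < 0.05 are kept and successive significant windows merge into
selection hotspots.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, ValidationError, merge_intervals

POPULATIONS = ("AFR", "AMR", "SAS", "EUR", "EAS")

POSSEL_METRICS = (("mean_daf", "upper"), ("delta_daf", "upper"), ("mean_abs_nsl", "upper"))
NEGSEL_METRICS = (("phylop", "upper"), ("pi", "lower"))


@dataclass
class SelectionConfig:
    tail_fraction: float = 0.05
    alpha: float = 0.05
    n_sims: int = 10_000
    n_deciles: int = 10
    negsel_rule: str = "or_filter"  # or "and_quantiles"
    min_defined: int = 20
    seed: int = 0


@dataclass
class SelectionHotspot:
    region: GenomicInterval
    mode: str  # PosSel | NegSel | BalSel
    metric: str  # comma-joined triggering metrics
    empirical_p: float | None
    n_windows: int = 1


# ---------------------------------------------------------------------------
# per-window statistics


def tile_genome_1kb(chrom_extents: dict[str, int], width: int = 1000) -> pd.DataFrame:
    """Non-overlapping 1-kb tiling used for selection and replication scans."""
    frames = []
    for chrom in sorted(chrom_extents):
        starts = np.arange(0, chrom_extents[chrom] - width + 1, width)
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + width}))
    return pd.concat(frames, ignore_index=True)


def _assign_windows(sites: pd.DataFrame, windows: pd.DataFrame) -> np.ndarray:
    """Window index per site (-1 when outside every window)."""
    out = np.full(len(sites), -1, dtype=np.int64)
    for chrom, wsub in windows.groupby("chrom", sort=False):
        sel = np.flatnonzero((sites["chrom"] == chrom).to_numpy())
        if len(sel) == 0:
            continue
        pos = sites["pos"].to_numpy()[sel]
        starts = wsub["start"].to_numpy()
        ends = wsub["end"].to_numpy()
        j = np.searchsorted(starts, pos, side="right") - 1
        ok = j >= 0
        ok[ok] &= pos[ok] < ends[j[ok]]
        out[sel[ok]] = wsub.index.to_numpy()[j[ok]]
    return out


def window_selection_stats(sites: pd.DataFrame, windows: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-site statistics over a non-overlapping window tiling.

    ``sites`` needs columns ``chrom, pos`` plus any of ``daf_<POP>``,
    ``nsl``, ``phylop``, ``maf``, ``n_alt``, ``n_total``.  Windows with
    no informative sites keep NaN (undefined), never zero.
    """
    windows = windows.reset_index(drop=True)
    widx = _assign_windows(sites, windows)
    s = sites.assign(_w=widx)
    s = s[s["_w"] >= 0]

    daf_cols = [c for c in sites.columns if c.startswith("daf_")]
    out = windows.copy()
    for col in ("mean_daf", "delta_daf", "mean_abs_nsl", "phylop", "pi", "mean_maf"):
        out[col] = np.nan
    out["n_informative"] = 0

    if len(s) == 0:
        return out

    if daf_cols:
        daf = s[daf_cols].to_numpy(dtype=float)
        site_daf = np.nanmean(daf, axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            site_delta = np.nanmax(daf, axis=1) - np.nanmin(daf, axis=1)
        n_pops = (~np.isnan(daf)).sum(axis=1)
        site_delta[n_pops < 2] = np.nan
    else:
        site_daf = np.full(len(s), np.nan)
        site_delta = np.full(len(s), np.nan)

    agg = pd.DataFrame(
        {
            "_w": s["_w"].to_numpy(),
            "site_daf": site_daf,
            "site_delta": site_delta,
            "abs_nsl": np.abs(s["nsl"].to_numpy(dtype=float)) if "nsl" in s else np.nan,
            "phylop": s["phylop"].to_numpy(dtype=float) if "phylop" in s else np.nan,
            "maf": s["maf"].to_numpy(dtype=float) if "maf" in s else np.nan,
        }
    )
    agg["informative"] = (~np.isnan(agg["site_daf"])) | (~np.isnan(agg["abs_nsl"]))
    g = agg.groupby("_w", sort=True)
    means = g[["site_daf", "site_delta", "abs_nsl", "phylop", "maf"]].mean()
    n_inf = g["informative"].sum()

    out.loc[means.index, "mean_daf"] = means["site_daf"].to_numpy()
    out.loc[means.index, "delta_daf"] = means["site_delta"].to_numpy()
    out.loc[means.index, "mean_abs_nsl"] = means["abs_nsl"].to_numpy()
    out.loc[means.index, "phylop"] = means["phylop"].to_numpy()
    out.loc[means.index, "mean_maf"] = means["maf"].to_numpy()
    out.loc[n_inf.index, "n_informative"] = n_inf.astype(int).to_numpy()

    if {"n_alt", "n_total"}.issubset(sites.columns):
        counts = s[["_w", "n_alt", "n_total"]].dropna()
        out["pi"] = _pi_from_counts(
            counts["_w"].to_numpy(dtype=np.int64),
            counts["n_alt"].to_numpy(dtype=float),
            counts["n_total"].to_numpy(dtype=float),
            len(windows),
            (windows["end"] - windows["start"]).to_numpy(),
        )
    return out


def _pi_from_counts(widx, n_alt, n_total, n_win, lengths) -> np.ndarray:
    if np.any(n_alt > n_total):
        raise ValidationError("n_alt exceeds n_total at some site")
    if np.any(n_total < 2):
        raise ValidationError("n_total must be >= 2 at every site")
    het = 2.0 * n_alt * (n_total - n_alt) / (n_total * (n_total - 1.0))
    pi = np.zeros(n_win)
    np.add.at(pi, widx, het)
    return pi / lengths


def nucleotide_diversity(
    site_allele_counts: pd.DataFrame,
    windows: pd.DataFrame,
) -> np.ndarray:
    """Per-bp nucleotide diversity pi for each window.

    pi_window = sum over sites of 2*n_alt*(n_total-n_alt) /
    (n_total*(n_total-1)), divided by window length.  Equals the mean
    pairwise difference count between haplotypes divided by length.
    """
    windows = windows.reset_index(drop=True)
    widx_all = _assign_windows(site_allele_counts, windows)
    keep = widx_all >= 0
    return _pi_from_counts(
        widx_all[keep],
        site_allele_counts["n_alt"].to_numpy(dtype=float)[keep],
        site_allele_counts["n_total"].to_numpy(dtype=float)[keep],
        len(windows),
        (windows["end"] - windows["start"]).to_numpy(),
    )


# ---------------------------------------------------------------------------
# earmarking and matched nulls


def earmark_candidates(
    values: np.ndarray | pd.Series,
    tail: str,
    fraction: float = 0.05,
    min_defined: int = 20,
) -> np.ndarray:
    """Boolean mask of windows at or beyond the tail quantile (ties kept)."""
    v = np.asarray(values, dtype=float)
    defined = ~np.isnan(v)
    n_def = int(defined.sum())
    if n_def == 0:
        raise ValidationError("metric undefined for every window")
    if n_def < min_defined:
        raise ValidationError(f"metric defined for only {n_def} windows (< {min_defined})")
    k = max(1, int(np.floor(n_def * fraction)))
    vals = v[defined]
    if tail == "upper":
        thresh = np.sort(vals)[::-1][k - 1]
        mask = defined & (v >= thresh)
    elif tail == "lower":
        thresh = np.sort(vals)[k - 1]
        mask = defined & (v <= thresh)
    else:
        raise ValidationError(f"tail must be upper/lower, got {tail!r}")
    if np.allclose(vals, vals[0]):
        warnings.warn("metric constant across windows; all windows earmarked")
    return mask


def decile_groups(n_informative: np.ndarray | pd.Series, n_deciles: int = 10) -> np.ndarray:
    """Rank-based decile index (0..9); tied counts share the lower decile."""
    n = np.asarray(n_informative)
    order = np.argsort(n, kind="stable")
    dec = np.empty(len(n), dtype=np.int64)
    dec[order] = np.arange(len(n)) * n_deciles // max(len(n), 1)
    # ties take the lowest decile of their value run
    sorted_vals = n[order]
    run_start = 0
    for i in range(1, len(n) + 1):
        if i == len(n) or sorted_vals[i] != sorted_vals[run_start]:
            dec[order[run_start:i]] = dec[order[run_start]]
            run_start = i
    return dec


def matched_null_pvalue(
    values: np.ndarray,
    deciles: np.ndarray,
    candidate: int,
    tail: str = "upper",
    n_sims: int = 10_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Empirical p for one candidate against its decile's null.

    p = (r+1)/(n_sims+1) where r counts resampled windows whose metric
    is at least (upper tail) or at most (lower tail) as extreme as the
    candidate.  Sampling is with replacement from the candidate's decile
    excluding the candidate itself; the count of extreme draws is
    binomial in the pool exceedance fraction, which is how it is drawn.
    """
    rng = rng or np.random.default_rng()
    return float(
        matched_null_pvalues(values, deciles, np.array([candidate]), tail, n_sims, rng)[0]
    )


def matched_null_pvalues(
    values: np.ndarray,
    deciles: np.ndarray,
    candidates: np.ndarray,
    tail: str = "upper",
    n_sims: int = 10_000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    rng = rng or np.random.default_rng()
    values = np.asarray(values, dtype=float)
    out = np.empty(len(candidates))
    pools: dict[int, np.ndarray] = {}
    for d in np.unique(deciles[candidates]):
        mask = (deciles == d) & ~np.isnan(values)
        pools[int(d)] = np.sort(values[mask])
    for i, c in enumerate(candidates):
        x = values[c]
        if np.isnan(x):
            raise ValidationError(f"candidate {c} has undefined metric")
        pool = pools[int(deciles[c])]
        m = len(pool) - 1  # candidate itself excluded
        if m < 1:
            raise ValidationError("empty decile pool")
        if tail == "upper":
            n_ge = len(pool) - np.searchsorted(pool, x, side="left") - 1
        else:
            n_ge = np.searchsorted(pool, x, side="right") - 1
        f = n_ge / m
        r = rng.binomial(n_sims, min(max(f, 0.0), 1.0))
        out[i] = (r + 1) / (n_sims + 1)
    return out


# ---------------------------------------------------------------------------
# hotspot calling


def _merge_windows(
    windows: pd.DataFrame,
    idx: np.ndarray,
    mode: str,
    metric_of: dict[int, set[str]],
    p_of: dict[int, float],
) -> list[SelectionHotspot]:
    calls: list[SelectionHotspot] = []
    sub = windows.loc[idx].sort_values(["chrom", "start"])
    group: list[int] = []

    def close() -> None:
        if not group:
            return
        rows = windows.loc[group]
        metrics = sorted(set().union(*(metric_of[g] for g in group)))
        calls.append(
            SelectionHotspot(
                region=GenomicInterval(
                    rows.iloc[0]["chrom"], int(rows["start"].min()), int(rows["end"].max())
                ),
                mode=mode,
                metric=",".join(metrics),
                empirical_p=min(p_of[g] for g in group),
                n_windows=len(group),
            )
        )

    prev_chrom, prev_end = None, None
    for i, row in sub.iterrows():
        if group and row["chrom"] == prev_chrom and row["start"] <= prev_end:
            group.append(i)
        else:
            close()
            group = [i]
        prev_chrom, prev_end = row["chrom"], int(row["end"])
    close()
    return calls


def call_selection_hotspots(
    stats: pd.DataFrame,
    mode: str,
    config: SelectionConfig | None = None,
) -> list[SelectionHotspot]:
    """Earmark, matched-null-test and merge windows into selection hotspots.

    ``stats`` is the output of :func:`window_selection_stats`.  PosSel
    uses the union over the three positive-selection metrics; NegSel
    either earmarks by each metric and filters (``or_filter``, default)
    or requires top-phyloP and bottom-pi at once (``and_quantiles``).
    """
    config = config or SelectionConfig()
    rng = np.random.default_rng(config.seed)
    deciles = decile_groups(stats["n_informative"].to_numpy(), config.n_deciles)

    if mode == "PosSel":
        metrics = POSSEL_METRICS
    elif mode == "NegSel":
        metrics = NEGSEL_METRICS
    else:
        raise ValidationError(f"mode must be PosSel or NegSel, got {mode!r}")

    sig_metric: dict[int, set[str]] = {}
    sig_p: dict[int, float] = {}
    per_metric_sig: list[set[int]] = []
    earmark_masks: list[np.ndarray] = []
    for metric, tail in metrics:
        values = stats[metric].to_numpy(dtype=float)
        if np.isnan(values).all():
            warnings.warn(f"{metric} undefined everywhere; metric skipped")
            per_metric_sig.append(set())
            earmark_masks.append(np.zeros(len(values), dtype=bool))
            continue
        mask = earmark_candidates(values, tail, config.tail_fraction, config.min_defined)
        earmark_masks.append(mask)
        cand = np.flatnonzero(mask)
        pvals = matched_null_pvalues(values, deciles, cand, tail, config.n_sims, rng)
        sig = cand[pvals < config.alpha]
        per_metric_sig.append(set(int(i) for i in sig))
        for i, p in zip(cand, pvals):
            if p < config.alpha:
                sig_metric.setdefault(int(i), set()).add(metric)
                sig_p[int(i)] = min(sig_p.get(int(i), 1.0), float(p))

    if mode == "NegSel" and config.negsel_rule == "and_quantiles":
        both_earmarked = earmark_masks[0] & earmark_masks[1]
        keep = per_metric_sig[0] & per_metric_sig[1] & set(np.flatnonzero(both_earmarked))
        sig_metric = {i: sig_metric[i] for i in keep}

    idx = np.array(sorted(sig_metric), dtype=int)
    if len(idx) == 0:
        return []
    return _merge_windows(stats, idx, mode, sig_metric, sig_p)


def merge_balancing_regions(
    region_sets: Iterable[Iterable[GenomicInterval]],
) -> list[SelectionHotspot]:
    """Merge balancing-selection regions across populations/target
    frequencies into disjoint BalSel hotspots."""
    flat = [iv for regions in region_sets for iv in regions]
    return [
        SelectionHotspot(region=iv, mode="BalSel", metric="balancing", empirical_p=None)
        for iv in merge_intervals(flat, merge_bookended=True)
    ]
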