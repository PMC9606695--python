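"""Genome-wide windowed methylation profiles and their correlates.

Covers the landscape-level analyses: tiling-window methylation levels (500-kb
windows for genome overviews, 100-kb windows for replicate reproducibility),
the relative proportion of methylcytosines per sequence context, correlations
of methylation with gene/TE density, and the TE-distance-to-gene methylation
trend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .calls import CONTEXTS, GeneModel, TEAnnotation


@dataclass
class WindowProfile:
    """Tiling-window methylation profile.

    ``table`` has one row per window with columns chrom, start, end (0-based
    half-open), one ``level_<context>`` column per context (NaN = MISSING),
    and optional ``gene_density`` (genes per window, by midpoint) and
    ``te_density`` (TE-bp fraction of the window).
    """

    window_size: int
    table: pd.DataFrame


def _window_frame(chrom_sizes: dict[str, int], window_size: int) -> pd.DataFrame:
    rows = []
    for chrom in sorted(chrom_sizes):
        size = int(chrom_sizes[chrom])
        starts = np.arange(0, size, window_size, dtype=np.int64)
        ends = np.minimum(starts + window_size, size)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def window_methylation(
    calls: pd.DataFrame,
    chrom_sizes: dict[str, int],
    window_size: int,
    contexts=CONTEXTS,
    min_coverage: int = 1,
) -> WindowProfile:
    """Weighted methylation level per non-overlapping tiling window.

    Windows tile each chromosome completely (trailing partial window kept);
    windows without qualifying sites get NaN for that context.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    frame = _window_frame(chrom_sizes, window_size)
    frame["_win"] = frame["start"] // window_size
    use = calls[calls["coverage"] >= min_coverage]
    win = (use["pos"].to_numpy() - 1) // window_size
    agg = (
        use.assign(_win=win)
        .groupby(["chrom", "_win", "context"], observed=True)[["methylated", "coverage"]]
        .sum()
    )
    level = (agg["methylated"] / agg["coverage"]).unstack("context")
    for ctx in contexts:
        if ctx not in level.columns:
            level[ctx] = np.nan
    level = level[list(contexts)]
    level.columns = [f"level_{c}" for c in contexts]
    out = frame.merge(level.reset_index(), on=["chrom", "_win"], how="left")
    out = out.drop(columns="_win")
    return WindowProfile(window_size, out)


def annotate_densities(
    profile: WindowProfile,
    genes: list[GeneModel],
    tes: list[TEAnnotation],
) -> WindowProfile:
    """Add gene density (count per window, by gene midpoint) and TE density
    (TE-bp / window-bp, overlaps clipped to the window) to a window profile."""
    table = profile.table.copy()
    w = profile.window_size
    key = {
        (chrom, start): i
        for i, (chrom, start) in enumerate(zip(table["chrom"], table["start"]))
    }
    gene_count = np.zeros(len(table), dtype=np.int64)
    for g in genes:
        mid = g.interval.midpoint
        idx = key.get((g.interval.chrom, (mid // w) * w))
        if idx is not None:
            gene_count[idx] += 1
    te_bp = np.zeros(len(table), dtype=np.int64)
    for te in tes:
        iv = te.interval
        first = iv.start // w
        last = (iv.end - 1) // w
        for b in range(first, last + 1):
            idx = key.get((iv.chrom, b * w))
            if idx is None:
                continue
            lo = max(iv.start, b * w)
            hi = min(iv.end, (b + 1) * w)
            te_bp[idx] += hi - lo
    table["gene_density"] = gene_count
    table["te_density"] = te_bp / (table["end"] - table["start"])
    return WindowProfile(w, table)


def replicate_correlation(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    chrom_sizes: dict[str, int],
    window_size: int = 100_000,
    context: str = "CG",
) -> float:
    """Pearson correlation of windowed methylation levels between replicates.

    Windows missing in either replicate are excluded pairwise; fewer than
    three complete pairs is an error.
    """
    col = f"level_{context}"
    a = window_methylation(calls_a, chrom_sizes, window_size, (context,)).table[col]
    b = window_methylation(calls_b, chrom_sizes, window_size, (context,)).table[col]
    ok = a.notna() & b.notna()
    if int(ok.sum()) < 3:
        raise ValueError("insufficient windows for replicate correlation")
    return float(stats.pearsonr(a[ok], b[ok])[0])


def context_proportions(
    calls: pd.DataFrame,
    site_call: str = "binomial",
    error_rate: float = 0.005,
    q_threshold: float = 0.05,
) -> dict[str, float]:
    """Share of methylcytosines per sequence context (sums to 1).

    A covered site counts as a methylcytosine under:

    * ``binomial`` (default): one-sided binomial test of methylated reads
      against the bisulfite non-conversion/error rate, BH-FDR < ``q_threshold``;
    * ``any_read``: at least one methylated read.
    """
    if len(calls) == 0:
        raise ValueError("empty call table")
    meth = calls["methylated"].to_numpy()
    cov = calls["coverage"].to_numpy()
    if site_call == "any_read":
        is_mc = meth > 0
    elif site_call == "binomial":
        if not (0.0 < error_rate < 1.0):
            raise ValueError("error_rate must be in (0, 1)")
        candidates = meth > 0  # sites with zero mC reads can never reject
        p = stats.binom.sf(meth[candidates] - 1, cov[candidates], error_rate)
        q = bh_adjust(p)
        is_mc = np.zeros(len(calls), dtype=bool)
        is_mc[np.flatnonzero(candidates)] = q < q_threshold
    else:
        raise ValueError(f"unknown site_call {site_call!r}")
    total = int(is_mc.sum())
    if total == 0:
        return {ctx: 0.0 for ctx in CONTEXTS}
    ctx_arr = calls["context"].to_numpy()
    return {ctx: float(is_mc[ctx_arr == ctx].sum() / total) for ctx in CONTEXTS}


def density_correlation(
    profile: WindowProfile, which: str, context: str
) -> tuple[float, float]:
    """Pearson r (and two-sided p) between a density column and a methylation
    level column over complete windows."""
    if which not in ("gene", "te"):
        raise ValueError("which must be 'gene' or 'te'")
    col = f"{which}_density"
    lvl = f"level_{context}"
    table = profile.table
    ok = table[lvl].notna() & table[col].notna()
    if int(ok.sum()) < 3:
        raise ValueError("insufficient windows")
    x = table.loc[ok, col].to_numpy(dtype=float)
    y = table.loc[ok, lvl].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def te_gene_distances(
    tes: list[TEAnnotation], genes: list[GeneModel]
) -> np.ndarray:
    """Distance (bp) from each TE to its nearest gene; 0 when overlapping."""
    if not genes:
        raise ValueError("no genes")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append(
            (g.interval.start, g.interval.end)
        )
    starts = {}
    ends = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts[chrom] = np.array([s for s, _ in ivs])
        ends[chrom] = np.maximum.accumulate(np.array([e for _, e in ivs]))
    out = np.empty(len(tes), dtype=np.int64)
    for i, te in enumerate(tes):
        chrom = te.interval.chrom
        if chrom not in starts:
            out[i] = np.iinfo(np.int64).max
            continue
        s, e = starts[chrom], ends[chrom]
        # nearest gene ending at/before TE start, nearest starting at/after end
        j = np.searchsorted(s, te.interval.end, side="left")
        gap_right = s[j] - te.interval.end if j < len(s) else np.iinfo(np.int64).max
        k = np.searchsorted(s, te.interval.start, side="right") - 1
        gap_left = te.interval.start - e[k] if k >= 0 else np.iinfo(np.int64).max
        out[i] = max(0, min(gap_left, gap_right))
    return out


def te_distance_profile(
    tes: list[TEAnnotation],
    genes: list[GeneModel],
    calls: pd.DataFrame,
    context: str = "CHH",
    distance_bins=(0, 500, 1000, 2000, 4000, 8000),
) -> pd.DataFrame:
    """Mean TE-body methylation level per TE-to-gene distance bin.

    ``distance_bins`` are increasing lower edges starting at 0; the last bin
    is open-ended.  Per bin the value is the mean over TEs of each TE's body
    weighted level (TEs with no covered site are skipped).
    """
    edges = list(distance_bins)
    if edges[0] != 0 or any(b >= c for b, c in zip(edges, edges[1:])):
        raise ValueError("distance_bins must be strictly increasing from 0")
    dist = te_gene_distances(tes, genes)
    sub = calls[calls["context"] == context]
    pos0 = sub["pos"].to_numpy() - 1
    meth = sub["methylated"].to_numpy()
    cov = sub["coverage"].to_numpy()
    chrom_arr = sub["chrom"].to_numpy()
    order = {}
    for chrom in np.unique(chrom_arr):
        m = chrom_arr == chrom
        order[chrom] = (pos0[m], meth[m], cov[m])
    levels = np.full(len(tes), np.nan)
    for i, te in enumerate(tes):
        got = order.get(te.interval.chrom)
        if got is None:
            continue
        p, mm, cc = got
        lo = np.searchsorted(p, te.interval.start)
        hi = np.searchsorted(p, te.interval.end)
        c = cc[lo:hi].sum()
        if c > 0:
            levels[i] = mm[lo:hi].sum() / c
    bin_idx = np.digitize(dist, edges[1:], right=False)
    rows = []
    for b in range(len(edges)):
        lo = edges[b]
        hi = edges[b + 1] if b + 1 < len(edges) else np.inf
        in_bin = (bin_idx == b) & ~np.isnan(levels)
        rows.append(
            {
                "dist_lo": lo,
                "dist_hi": hi,
                "n_tes": int(in_bin.sum()),
                "mean_level": float(np.mean(levels[in_bin])) if in_bin.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)


def write_profile_tsv(profile: WindowProfile, path) -> None:
    """Windowed profile TSV with 1-based inclusive start (external convention)."""
    table = profile.table.copy()
    table["start"] = table["start"] + 1
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
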