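"""DNA methylation valley (DMV) detection and characterization.

A DMV is a run of 1-kb bins in which the weighted methylation level of *every*
sequence context (CG, CHG and CHH) is below 5% in *every* tissue.  Qualifying
bins are intersected across tissues, contiguous/overlapping bins merged into
maximal intervals, and genes whose body plus 1-kb flanks lie inside a merged
DMV become DMV genes.  Bins lacking coverage in any context are non-qualifying:
absence of evidence is not hypomethylation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calls import CONTEXTS, GeneModel, GenomicInterval

Bin = tuple[str, int]  # (chrom, bin start in bp)


def scan_dmv_bins(
    calls_by_tissue: dict[str, pd.DataFrame],
    chrom_sizes: dict[str, int],
    bin_size: int = 1000,
    max_level: float = 0.05,
    min_reads: int = 5,
) -> tuple[dict[str, set], set]:
    """Qualifying hypomethylated bins per tissue and their all-tissue
    intersection.

    A bin qualifies for a tissue iff each context has >= ``min_reads`` pooled
    reads and a weighted level strictly below ``max_level``.  Returns
    ``(per_tissue_bins, intersection)`` as sets of (chrom, start).
    """
    if not calls_by_tissue:
        raise ValueError("at least one tissue required")
    per_tissue: dict[str, set] = {}
    for tissue, calls in calls_by_tissue.items():
        start = ((calls["pos"].to_numpy() - 1) // bin_size) * bin_size
        agg = (
            calls.assign(_start=start)
            .groupby(["chrom", "_start", "context"], observed=True)[
                ["methylated", "coverage"]
            ]
            .sum()
        )
        level = agg["methylated"] / agg["coverage"]
        ok = (level < max_level) & (agg["coverage"] >= min_reads)
        wide = ok.unstack("context").reindex(columns=list(CONTEXTS))
        qual = wide.eq(True).all(axis=1)  # NaN (absent context) never qualifies
        # all three contexts must be present with enough reads
        n_ctx = agg.groupby(["chrom", "_start"]).size()
        qual &= n_ctx.reindex(qual.index).fillna(0) >= len(CONTEXTS)
        per_tissue[tissue] = {
            (chrom, int(s)) for (chrom, s), q in qual.items() if q
        }
    tissues = list(per_tissue)
    inter = set(per_tissue[tissues[0]])
    for t in tissues[1:]:
        inter &= per_tissue[t]
    return per_tissue, inter


def merge_dmvs(bins: set, bin_size: int = 1000) -> list[GenomicInterval]:
    """Merge adjacent (book-ended) and overlapping qualifying bins into
    maximal runs; output sorted and pairwise disjoint.  Idempotent."""
    by_chrom: dict[str, list[int]] = {}
    for chrom, start in bins:
        by_chrom.setdefault(chrom, []).append(start)
    out = []
    for chrom in sorted(by_chrom):
        starts = sorted(by_chrom[chrom])
        run_start = starts[0]
        run_end = starts[0] + bin_size
        for s in starts[1:]:
            if s <= run_end:
                run_end = max(run_end, s + bin_size)
            else:
                out.append(GenomicInterval(chrom, run_start, run_end))
                run_start, run_end = s, s + bin_size
        out.append(GenomicInterval(chrom, run_start, run_end))
    return out


def merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Union of arbitrary intervals (adjacent or overlapping runs merged)."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda v: v.start)
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def intersect_interval_sets(sets: list[list[GenomicInterval]]) -> list[GenomicInterval]:
    """bp-level intersection of several interval sets (each first unioned)."""
    current = merge_intervals(sets[0])
    for other in sets[1:]:
        other = merge_intervals(other)
        result = []
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in other:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for iv in current:
            for o in by_chrom.get(iv.chrom, []):
                lo = max(iv.start, o.start)
                hi = min(iv.end, o.end)
                if hi > lo:
                    result.append(GenomicInterval(iv.chrom, lo, hi))
        current = merge_intervals(result) if result else []
        if not current:
            break
    return current


def assign_dmv_genes(
    dmvs: list[GenomicInterval],
    genes: list[GeneModel],
    flank_bp: int = 1000,
    mode: str = "contained",
) -> dict[int, set]:
    """Genes belonging to each DMV (keyed by DMV index).

    ``contained`` (default): the gene body expanded by ``flank_bp`` on both
    sides must lie entirely inside the DMV; ``overlap``: any overlap of the
    expanded gene span with the DMV suffices.
    """
    if mode not in ("contained", "overlap"):
        raise ValueError(f"unknown mode {mode!r}")
    out: dict[int, set] = {i: set() for i in range(len(dmvs))}
    for g in genes:
        span = g.interval.expanded(flank_bp)
        for i, dmv in enumerate(dmvs):
            if mode == "contained":
                if dmv.contains(span):
                    out[i].add(g.gene_id)
            else:
                if dmv.overlaps(span):
                    out[i].add(g.gene_id)
    return out


def tf_enrichment(
    dmv_gene_ids: set,
    all_gene_ids: set,
    tf_gene_ids: set,
) -> dict:
    """Chi-squared test (1 df, no continuity correction) of TF over-
    representation among DMV genes versus non-DMV genes.

    Falls back to Fisher's exact test (with a warning flag) when any expected
    cell is below 1.  Returns the 2x2 table, statistic, p-value, and the TF
    proportion inside/outside DMV genes.
    """
    if not tf_gene_ids <= all_gene_ids or not dmv_gene_ids <= all_gene_ids:
        raise ValueError("gene sets must be subsets of the gene universe")
    in_dmv_tf = len(dmv_gene_ids & tf_gene_ids)
    in_dmv_nontf = len(dmv_gene_ids) - in_dmv_tf
    out_genes = all_gene_ids - dmv_gene_ids
    out_tf = len(out_genes & tf_gene_ids)
    out_nontf = len(out_genes) - out_tf
    table = np.array([[in_dmv_tf, in_dmv_nontf], [out_tf, out_nontf]], dtype=float)
    prop_dmv = in_dmv_tf / max(len(dmv_gene_ids), 1)
    prop_other = out_tf / max(len(out_genes), 1)
    expected = stats.contingency.expected_freq(table) if table.sum() else table
    fallback = bool(table.sum() == 0 or (expected < 1).any())
    if fallback:
        _, p = stats.fisher_exact(table.astype(int))
        statistic = np.nan
    else:
        statistic, p, _, _ = stats.chi2_contingency(table, correction=False)
    return {
        "table": table.astype(int),
        "statistic": float(statistic) if statistic == statistic else np.nan,
        "p": float(p),
        "proportion_dmv": float(prop_dmv),
        "proportion_other": float(prop_other),
        "fisher_fallback": fallback,
    }


def tf_proportion_percent(n_tf: int, n_genes: int) -> int:
    """TF share of a gene set as a whole-number percentage
    (e.g. 136 TFs of 488 sucrose-metabolism valley genes -> 28)."""
    if n_genes <= 0 or n_tf < 0 or n_tf > n_genes:
        raise ValueError("invalid counts")
    return int(round(100.0 * n_tf / n_genes))


def dmv_summary(
    dmvs_per_tissue: dict[str, list[GenomicInterval]],
    genome_size: int,
) -> dict:
    """Per-tissue DMV counts, the shared (all-tissue) set, the non-redundant
    union, total bp, and genome fraction.

    The shared percentage is reported against every candidate denominator
    (each tissue's count and the non-redundant count).
    """
    counts = {t: len(v) for t, v in dmvs_per_tissue.items()}
    shared = intersect_interval_sets(list(dmvs_per_tissue.values()))
    nonredundant = merge_intervals(
        [iv for ivs in dmvs_per_tissue.values() for iv in ivs]
    )
    nr_bp = sum(iv.length for iv in nonredundant)
    shared_pct = {
        f"pct_of_{t}": 100.0 * len(shared) / c if c else np.nan
        for t, c in counts.items()
    }
    shared_pct["pct_of_nonredundant"] = (
        100.0 * len(shared) / len(nonredundant) if nonredundant else np.nan
    )
    return {
        "counts_per_tissue": counts,
        "shared_count": len(shared),
        "shared": shared,
        "nonredundant_count": len(nonredundant),
        "nonredundant": nonredundant,
        "nonredundant_bp": int(nr_bp),
        "genome_fraction": nr_bp / genome_size if genome_size else np.nan,
        "shared_percent_candidates": shared_pct,
    }


def write_dmv_bed(dmvs: list[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(dmvs, 1):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tDMV{i:05d}\t{iv.length}\t.\n")


def write_dmv_genes_tsv(dmv_genes: dict[int, set], mode: str, path) -> None:
    rows = []
    for i in sorted(dmv_genes):
        for gid in sorted(dmv_genes[i]):
            rows.append({"dmv_id": f"DMV{i + 1:05d}", "gene_id": gid, "mode": mode})
    pd.DataFrame(rows, columns=["dmv_id", "gene_id", "mode"]).to_csv(
        path, sep="\t", index=False
    )
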