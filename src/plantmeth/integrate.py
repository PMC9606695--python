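"""DMR-DEG association and flat term-map enrichment.

Connects the methylation and expression halves of the analysis: which genes
carry a DMR in their body or flanks, whether DMR-carrying genes are more
likely to be differentially expressed (2x2 association test), and generic
over-representation analysis of gene sets against a user-supplied flat
gene -> terms map (one-sided hypergeometric with BH-FDR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .calls import GeneModel


@dataclass
class AssociationResult:
    comparison: str
    table: np.ndarray             # [[DE & DMR, DE & no-DMR], [not-DE & DMR, not-DE & no-DMR]]
    proportion_deg_with_dmr: float
    p: float
    odds_ratio: float
    method: str                   # "chi2" or "fisher"


def dmr_gene_overlap(
    dmrs: pd.DataFrame,
    genes: list[GeneModel],
    flank_bp: int = 2000,
) -> set:
    """Gene ids whose body or +/- ``flank_bp`` flanks overlap any DMR."""
    if len(dmrs) == 0:
        return set()
    by_chrom = {}
    for chrom, grp in dmrs.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy(dtype=np.int64)
        ends = grp["end"].to_numpy(dtype=np.int64)
        order = np.argsort(starts, kind="mergesort")
        by_chrom[str(chrom)] = (starts[order], np.maximum.accumulate(ends[order]))
    hits = set()
    for g in genes:
        span = g.interval.expanded(flank_bp)
        got = by_chrom.get(span.chrom)
        if got is None:
            continue
        starts, cummax_ends = got
        j = np.searchsorted(starts, span.end, side="left")
        if j > 0 and cummax_ends[j - 1] > span.start:
            hits.add(g.gene_id)
    return hits


def deg_dmr_association(
    deg_ids: set,
    dmr_gene_ids: set,
    all_gene_ids: set,
    comparison: str = "",
) -> AssociationResult:
    """2x2 association of DE status x DMR-overlap status across the gene
    universe; chi-squared (1 df, no continuity correction), with Fisher's
    exact fallback when any expected cell is below 5."""
    if not all_gene_ids:
        raise ValueError("empty gene universe")
    if not deg_ids <= all_gene_ids or not dmr_gene_ids <= all_gene_ids:
        raise ValueError("gene sets must be subsets of the gene universe")
    a = len(deg_ids & dmr_gene_ids)
    b = len(deg_ids) - a
    c = len(dmr_gene_ids) - a
    d = len(all_gene_ids) - a - b - c
    table = np.array([[a, b], [c, d]], dtype=float)
    if table.sum() == 0:
        raise ValueError("empty table")
    expected = stats.contingency.expected_freq(table)
    if (expected < 5).any():
        method = "fisher"
        _, p = stats.fisher_exact(table.astype(int))
    else:
        method = "chi2"
        _, p, _, _ = stats.chi2_contingency(table, correction=False)
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    proportion = a / len(deg_ids) if deg_ids else np.nan
    return AssociationResult(comparison, table.astype(int), float(proportion),
                             float(p), float(odds), method)


def term_enrichment(
    gene_set: set,
    background: set,
    term_map: dict,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of flat terms in ``gene_set`` against
    ``background``.

    ``term_map`` maps gene id -> iterable of term ids.  Per term with at least
    one hit in the gene set: one-sided hypergeometric p
    (P[X >= k] with N = |background|, n = term genes in background,
    K = |gene_set|), BH-FDR across tested terms.
    """
    if not background:
        raise ValueError("empty background")
    if not gene_set <= background:
        raise ValueError("gene_set must be a subset of background")
    term_genes: dict[str, set] = {}
    for gid in background:
        for term in term_map.get(gid, ()):
            term_genes.setdefault(term, set()).add(gid)
    N = len(background)
    K = len(gene_set)
    rows = []
    for term in sorted(term_genes):
        members = term_genes[term]
        k = len(members & gene_set)
        if k == 0:
            continue
        n = len(members)
        p = float(stats.hypergeom.sf(k - 1, N, n, K))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p": p})
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["q"] < q_threshold
        out = out.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
    else:
        out["q"] = []
        out["significant"] = []
    return out


def read_term_map(path) -> tuple[dict, dict]:
    """Read a term map TSV (gene_id, term_id, term_name) into
    (gene -> set of term ids, term id -> name)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "term_id"}
    if not required <= set(df.columns):
        raise ValueError("term map needs gene_id and term_id columns")
    gene_terms: dict[str, set] = {}
    for row in df.itertuples():
        gene_terms.setdefault(row.gene_id, set()).add(row.term_id)
    names = {}
    if "term_name" in df.columns:
        names = dict(zip(df["term_id"], df["term_name"]))
    return gene_terms, names


def write_association_tsv(results: list[AssociationResult], path) -> None:
    rows = []
    for r in results:
        rows.append(
            {
                "comparison": r.comparison,
                "deg_with_dmr": r.table[0, 0],
                "deg_without_dmr": r.table[0, 1],
                "nondeg_with_dmr": r.table[1, 0],
                "nondeg_without_dmr": r.table[1, 1],
                "proportion_deg_with_dmr": r.proportion_deg_with_dmr,
                "odds_ratio": r.odds_ratio,
                "p": r.p,
                "method": r.method,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
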