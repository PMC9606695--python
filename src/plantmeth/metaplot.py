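"""Scaled metaplots over genes/TEs and methylation-expression association.

A metaplot averages methylation over a set of features after mapping each
feature body onto a fixed number of equal-width bins (length normalization)
and adding fixed-width flanking windows; minus-strand features are flipped so
bins always run 5' to 3'.  Pooling is *weighted*: methylated and total read
counts are summed across features per bin and ratioed at the end, which is
robust at low per-feature coverage (and deliberately differs from averaging
per-feature ratios).

The expression-association half groups genes by FPKM (expressed/unexpressed,
or the four FPKM clusters), compares group metaplots, and runs Wilcoxon
rank-sum tests between methylation quartiles or expression groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import wilcoxon_rank_sum
from .calls import GeneModel, GenomicInterval

REGIONS = ("upstream", "body", "downstream", "promoter")

#: FPKM cluster boundaries: C1 = 0, C2 (0, 2], C3 (2, 10], C4 (10, inf).
CLUSTER_EDGES = (0.0, 2.0, 10.0)


@dataclass
class MetaProfile:
    group_label: str
    upstream_bins: int
    body_bins: int
    downstream_bins: int
    meth: np.ndarray
    cov: np.ndarray
    n_features: int

    @property
    def values(self) -> np.ndarray:
        """Per-bin weighted levels (NaN where no coverage)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.cov > 0, self.meth / np.maximum(self.cov, 1e-300), np.nan)

    @property
    def n_bins(self) -> int:
        return self.upstream_bins + self.body_bins + self.downstream_bins

    def segment_slices(self):
        u, b = self.upstream_bins, self.body_bins
        return {
            "up": slice(0, u),
            "body": slice(u, u + b),
            "down": slice(u + b, self.n_bins),
        }


@dataclass
class ExpressionGroup:
    label: str
    gene_ids: set
    rule: str = ""


def _context_arrays(calls: pd.DataFrame, context: str | None):
    sub = calls if context is None else calls[calls["context"] == context]
    out = {}
    for chrom, grp in sub.groupby("chrom", sort=False):
        pos0 = grp["pos"].to_numpy(dtype=np.int64) - 1
        order = np.argsort(pos0, kind="mergesort")
        out[str(chrom)] = (
            pos0[order],
            grp["methylated"].to_numpy(dtype=np.float64)[order],
            grp["coverage"].to_numpy(dtype=np.float64)[order],
        )
    return out


def _accumulate_flank(pos0, meth, cov, rs, flank_bp, nbins, acc_m, acc_c, offset):
    lo = np.searchsorted(pos0, rs)
    hi = np.searchsorted(pos0, rs + flank_bp)
    if hi <= lo:
        return
    idx = ((pos0[lo:hi] - rs) * nbins) // flank_bp
    np.add.at(acc_m, offset + idx, meth[lo:hi])
    np.add.at(acc_c, offset + idx, cov[lo:hi])


def _accumulate_body(pos0, meth, cov, start, end, nbins, acc_m, acc_c, offset):
    """Distribute each 1-bp cytosine across scaled body bins by fractional
    overlap (a site can span several bins when the body is shorter than the
    bin count).

    Overlaps are computed in integer units (positions scaled by the bin count
    against bin edges scaled by the body length), so weights are exact and a
    mirrored minus-strand fixture reproduces a plus-strand profile bit for
    bit."""
    i0 = np.searchsorted(pos0, start)
    i1 = np.searchsorted(pos0, end)
    if i1 <= i0:
        return
    length = int(end - start)
    s = (pos0[i0:i1] - start).astype(np.int64)
    lo = s * nbins               # scaled span [lo, lo + nbins)
    hi = lo + nbins
    f = np.minimum(lo // length, nbins - 1)
    single = hi <= (f + 1) * length
    np.add.at(acc_m, offset + f[single], meth[i0:i1][single])
    np.add.at(acc_c, offset + f[single], cov[i0:i1][single])
    for j in np.flatnonzero(~single):
        first = int(f[j])
        last = min(int((hi[j] - 1) // length), nbins - 1)
        for k in range(first, last + 1):
            overlap = min(int(hi[j]), (k + 1) * length) - max(int(lo[j]), k * length)
            if overlap <= 0:
                continue
            w = overlap / nbins
            acc_m[offset + k] += w * meth[i0 + j]
            acc_c[offset + k] += w * cov[i0 + j]


def metaplot(
    calls: pd.DataFrame,
    features,
    context: str | None,
    flank_bp: int = 2000,
    body_bins: int = 20,
    flank_bins: int = 20,
    group_label: str = "all",
) -> MetaProfile:
    """Weighted-pooling metaplot over gene or TE features.

    ``features`` is a sequence of objects with an ``interval`` attribute and
    an optional ``strand`` ('+' assumed when absent, e.g. TEs).
    """
    if flank_bp < 0 or body_bins < 1 or flank_bins < 1:
        raise ValueError("invalid metaplot binning parameters")
    arrays = _context_arrays(calls, context)
    nb = flank_bins + body_bins + flank_bins
    total_m = np.zeros(nb)
    total_c = np.zeros(nb)
    n_feat = 0
    for feat in features:
        iv: GenomicInterval = feat.interval
        strand = getattr(feat, "strand", "+")
        got = arrays.get(iv.chrom)
        n_feat += 1
        if got is None:
            continue
        pos0, meth, cov = got
        acc_m = np.zeros(nb)
        acc_c = np.zeros(nb)
        if flank_bp > 0:
            _accumulate_flank(
                pos0, meth, cov, iv.start - flank_bp, flank_bp, flank_bins,
                acc_m, acc_c, 0,
            )
            _accumulate_flank(
                pos0, meth, cov, iv.end, flank_bp, flank_bins,
                acc_m, acc_c, flank_bins + body_bins,
            )
        _accumulate_body(
            pos0, meth, cov, iv.start, iv.end, body_bins, acc_m, acc_c, flank_bins
        )
        if strand == "-":
            acc_m = acc_m[::-1]
            acc_c = acc_c[::-1]
        total_m += acc_m
        total_c += acc_c
    return MetaProfile(group_label, flank_bins, body_bins, flank_bins,
                       total_m, total_c, n_feat)


def gene_te_body_overlap(genes, tes) -> dict[str, int]:
    """TE bp overlapping each gene body (0 for TE-free genes)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for te in tes:
        by_chrom.setdefault(te.interval.chrom, []).append(
            (te.interval.start, te.interval.end)
        )
    sorted_tes = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        sorted_tes[chrom] = (
            np.array([s for s, _ in ivs]),
            np.array([e for _, e in ivs]),
        )
    out = {}
    for g in genes:
        iv = g.interval
        bp = 0
        got = sorted_tes.get(iv.chrom)
        if got is not None:
            s, e = got
            for j in range(len(s)):
                if s[j] >= iv.end:
                    break
                if e[j] > iv.start:
                    bp += min(e[j], iv.end) - max(s[j], iv.start)
        out[g.gene_id] = int(bp)
    return out


def metaplot_excluding_te_genes(
    calls: pd.DataFrame,
    genes,
    tes,
    context: str | None,
    **kwargs,
):
    """Metaplot over all genes and over the subset whose body overlaps no TE.

    Returns ``(all_profile, te_free_profile, excluded_fraction)``.
    """
    overlap = gene_te_body_overlap(genes, tes)
    te_free = [g for g in genes if overlap[g.gene_id] == 0]
    if not te_free:
        raise ValueError("all genes carry TE overlap; nothing to compare")
    prof_all = metaplot(calls, genes, context, group_label="all_genes", **kwargs)
    prof_free = metaplot(calls, te_free, context, group_label="te_free_genes", **kwargs)
    excluded_fraction = 1.0 - len(te_free) / len(genes)
    return prof_all, prof_free, excluded_fraction


# ---------------------------------------------------------------------------
# expression grouping
# ---------------------------------------------------------------------------

def group_by_expression(fpkm: pd.Series, scheme: str = "binary") -> list[ExpressionGroup]:
    """Partition genes by FPKM.

    ``binary``: expressed (FPKM >= 1) vs unexpressed (FPKM < 1).
    ``clusters``: Cluster1 FPKM = 0, Cluster2 (0, 2], Cluster3 (2, 10],
    Cluster4 > 10.
    """
    if (fpkm < 0).any():
        raise ValueError("negative FPKM")
    if scheme == "binary":
        expressed = set(fpkm.index[fpkm >= 1.0])
        unexpressed = set(fpkm.index[fpkm < 1.0])
        return [
            ExpressionGroup("expressed", expressed, "FPKM >= 1"),
            ExpressionGroup("unexpressed", unexpressed, "FPKM < 1"),
        ]
    if scheme == "clusters":
        c1, c2, c3 = CLUSTER_EDGES
        return [
            ExpressionGroup("Cluster1", set(fpkm.index[fpkm == c1]), "FPKM = 0"),
            ExpressionGroup(
                "Cluster2", set(fpkm.index[(fpkm > c1) & (fpkm <= c2)]), "0 < FPKM <= 2"
            ),
            ExpressionGroup(
                "Cluster3", set(fpkm.index[(fpkm > c2) & (fpkm <= c3)]), "2 < FPKM <= 10"
            ),
            ExpressionGroup("Cluster4", set(fpkm.index[fpkm > c3]), "FPKM > 10"),
        ]
    raise ValueError(f"unknown scheme {scheme!r}")


def group_metaplots(
    calls: pd.DataFrame,
    genes,
    groups: list[ExpressionGroup],
    context: str | None,
    **kwargs,
) -> dict[str, MetaProfile]:
    """One metaplot per expression group (computed on that group's genes)."""
    by_id = {g.gene_id: g for g in genes}
    out = {}
    for grp in groups:
        members = [by_id[g] for g in sorted(grp.gene_ids) if g in by_id]
        if not members:
            nb = kwargs.get("flank_bins", 20) * 2 + kwargs.get("body_bins", 20)
            out[grp.label] = MetaProfile(
                grp.label, kwargs.get("flank_bins", 20), kwargs.get("body_bins", 20),
                kwargs.get("flank_bins", 20), np.zeros(nb), np.zeros(nb), 0,
            )
            continue
        out[grp.label] = metaplot(calls, members, context, group_label=grp.label, **kwargs)
    return out


# ---------------------------------------------------------------------------
# per-gene region levels and rank-sum tests
# ---------------------------------------------------------------------------

def _gene_region(g: GeneModel, region: str, flank_bp: int,
                 promoter_window: tuple[int, int] = (200, 2000)) -> GenomicInterval | None:
    iv = g.interval
    near, far = promoter_window
    if region == "body":
        return iv
    if g.strand == "+":
        if region == "upstream":
            lo, hi = iv.start - flank_bp, iv.start
        elif region == "downstream":
            lo, hi = iv.end, iv.end + flank_bp
        else:  # promoter: -far..-near from TSS
            lo, hi = iv.start - far, iv.start - near
    else:
        if region == "upstream":
            lo, hi = iv.end, iv.end + flank_bp
        elif region == "downstream":
            lo, hi = iv.start - flank_bp, iv.start
        else:
            lo, hi = iv.end + near, iv.end + far
    lo = max(0, lo)
    if hi <= lo:
        return None
    return GenomicInterval(iv.chrom, lo, hi)


def region_methylation(
    calls: pd.DataFrame,
    genes,
    region: str = "body",
    context: str | None = None,
    flank_bp: int = 2000,
) -> pd.Series:
    """Per-gene weighted methylation level of a genic region
    (upstream / body / downstream / promoter).  NaN = no covered site."""
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}")
    arrays = _context_arrays(calls, context)
    out = {}
    for g in genes:
        riv = _gene_region(g, region, flank_bp)
        level = np.nan
        if riv is not None:
            got = arrays.get(riv.chrom)
            if got is not None:
                pos0, meth, cov = got
                lo = np.searchsorted(pos0, riv.start)
                hi = np.searchsorted(pos0, riv.end)
                c = cov[lo:hi].sum()
                if c > 0:
                    level = meth[lo:hi].sum() / c
        out[g.gene_id] = level
    return pd.Series(out, name=f"{region}_{context or 'ALL'}")


def quartile_expression_test(
    calls: pd.DataFrame,
    genes,
    fpkm: pd.Series,
    region: str = "body",
    context: str | None = None,
    flank_bp: int = 2000,
) -> dict:
    """Split genes into methylation quartiles for a genic region and test FPKM
    differences between every quartile pair with the Wilcoxon rank-sum test.

    Q1 holds the least methylated 25% of genes, Q4 the most methylated; ties
    are broken deterministically by gene id.  Returns quartile memberships,
    median FPKM per quartile, and pairwise two-sided p-values.
    """
    levels = region_methylation(calls, genes, region, context, flank_bp)
    levels = levels[levels.notna()]
    levels = levels[levels.index.isin(fpkm.index)]
    if len(levels) < 8:
        raise ValueError("too few genes with region methylation for quartiles")
    ordered = levels.reset_index().rename(columns={"index": "gene_id", levels.name: "level"})
    ordered = ordered.sort_values(["level", "gene_id"], kind="mergesort")
    parts = np.array_split(ordered["gene_id"].to_numpy(), 4)
    quartiles = {f"Q{i + 1}": list(part) for i, part in enumerate(parts)}
    median_fpkm = {q: float(fpkm.loc[ids].median()) for q, ids in quartiles.items()}
    pvalues = {}
    names = list(quartiles)
    for i in range(4):
        for j in range(i + 1, 4):
            p = wilcoxon_rank_sum(
                fpkm.loc[quartiles[names[i]]].to_numpy(),
                fpkm.loc[quartiles[names[j]]].to_numpy(),
            )
            pvalues[(names[i], names[j])] = p
    return {
        "quartiles": quartiles,
        "median_fpkm": median_fpkm,
        "pvalues": pvalues,
        "levels": levels,
    }


def expressed_vs_unexpressed_test(
    calls: pd.DataFrame,
    genes,
    groups: list[ExpressionGroup],
    region: str = "upstream",
    context: str | None = None,
    flank_bp: int = 2000,
) -> dict:
    """Wilcoxon rank-sum test of per-gene region methylation between two
    expression groups; returns per-group mean level, the difference
    (first minus second), and the two-sided p-value."""
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    levels = region_methylation(calls, genes, region, context, flank_bp)
    samples = []
    means = {}
    for grp in groups:
        vals = levels[levels.index.isin(grp.gene_ids)].dropna().to_numpy()
        if vals.size == 0:
            raise ValueError(f"group {grp.label} has no genes with data")
        samples.append(vals)
        means[grp.label] = float(vals.mean())
    p = wilcoxon_rank_sum(samples[0], samples[1])
    return {
        "means": means,
        "difference": float(samples[0].mean() - samples[1].mean()),
        "p": p,
        "n": (int(samples[0].size), int(samples[1].size)),
    }


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def metaprofile_table(profiles: dict[str, MetaProfile]) -> pd.DataFrame:
    rows = []
    for label, prof in profiles.items():
        vals = prof.values
        segs = prof.segment_slices()
        for seg, sl in segs.items():
            for k in range(sl.start, sl.stop):
                rows.append(
                    {
                        "group": label,
                        "bin_index": k,
                        "segment": seg,
                        "level": vals[k],
                        "n_features": prof.n_features,
                    }
                )
    return pd.DataFrame(rows)


def write_metaprofile_tsv(profiles: dict[str, MetaProfile], path) -> None:
    metaprofile_table(profiles).to_csv(path, sep="\t", index=False, float_format="%.6g")


def plot_metaprofiles(profiles: dict[str, MetaProfile], path, title: str = "") -> None:
    """Simple line-chart rendering of one or more metaprofiles."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, prof in profiles.items():
        ax.plot(np.arange(prof.n_bins), prof.values, label=label)
    first = next(iter(profiles.values()))
    ax.axvline(first.upstream_bins - 0.5, color="grey", lw=0.5)
    ax.axvline(first.upstream_bins + first.body_bins - 0.5, color="grey", lw=0.5)
    ax.set_xlabel("bin (5' flank | body | 3' flank)")
    ax.set_ylabel("methylation level")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
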