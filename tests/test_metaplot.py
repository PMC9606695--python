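"""Metaplots, expression grouping, and methylation-expression tests."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from plantmeth._stats import wilcoxon_rank_sum
from plantmeth.calls import GeneModel, GenomicInterval, TEAnnotation
from plantmeth.metaplot import (
    expressed_vs_unexpressed_test,
    group_by_expression,
    group_metaplots,
    metaplot,
    metaplot_excluding_te_genes,
    quartile_expression_test,
    region_methylation,
)
from conftest import make_calls


def _oracle_metaplot(calls, features, context, flank_bp=2000, body_bins=20, flank_bins=20):
    """Independent per-site pooling oracle: explicit interval-overlap weights,
    no shared code with the implementation."""
    nb = 2 * flank_bins + body_bins
    meth = np.zeros(nb)
    cov = np.zeros(nb)
    sub = calls[calls["context"] == context] if context else calls
    for feat in features:
        iv = feat.interval
        strand = getattr(feat, "strand", "+")
        acc_m = np.zeros(nb)
        acc_c = np.zeros(nb)
        for r in sub.itertuples():
            if r.chrom != iv.chrom:
                continue
            p = r.pos - 1
            if iv.start - flank_bp <= p < iv.start and flank_bp > 0:
                k = int((p - (iv.start - flank_bp)) * flank_bins // flank_bp)
                acc_m[k] += r.methylated
                acc_c[k] += r.coverage
            elif iv.end <= p < iv.end + flank_bp and flank_bp > 0:
                k = flank_bins + body_bins + int((p - iv.end) * flank_bins // flank_bp)
                acc_m[k] += r.methylated
                acc_c[k] += r.coverage
            elif iv.start <= p < iv.end:
                a = (p - iv.start) * body_bins / iv.length
                b = (p + 1 - iv.start) * body_bins / iv.length
                for k in range(body_bins):
                    w = max(0.0, min(b, k + 1) - max(a, k)) / (b - a)
                    acc_m[flank_bins + k] += w * r.methylated
                    acc_c[flank_bins + k] += w * r.coverage
        if strand == "-":
            acc_m, acc_c = acc_m[::-1], acc_c[::-1]
        meth += acc_m
        cov += acc_c
    with np.errstate(invalid="ignore"):
        return np.where(cov > 0, meth / np.maximum(cov, 1e-300), np.nan)


def _uniform_calls(span, step=25, meth=4, cov=10, context="CG"):
    return make_calls([("chr1", p, "+", context, meth, cov) for p in range(1, span, step)])


def test_uniform_methylome_is_flat():
    calls = _uniform_calls(20_000)
    genes = [GeneModel("g1", GenomicInterval("chr1", 5000, 9000), "+"),
             GeneModel("g2", GenomicInterval("chr1", 12_000, 15_000), "-")]
    prof = metaplot(calls, genes, "CG")
    vals = prof.values
    assert np.allclose(vals[~np.isnan(vals)], 0.4)


def test_metaplot_locality_first_body_decile():
    gene = GeneModel("g1", GenomicInterval("chr1", 1000, 3000), "+")
    rows = [("chr1", p, "+", "CG", 9, 10) for p in range(1001, 1150, 10)]
    prof = metaplot(make_calls(rows), [gene], "CG", flank_bp=500)
    vals = prof.values
    body = vals[prof.upstream_bins : prof.upstream_bins + prof.body_bins]
    assert body[0] == pytest.approx(0.9)
    assert np.isnan(body[2:]).all()


def test_metaplot_matches_brute_force_oracle(rng):
    genes = [
        GeneModel("g1", GenomicInterval("chr1", 3000, 5200), "+"),
        GeneModel("g2", GenomicInterval("chr1", 8000, 8013), "+"),   # shorter than bins
        GeneModel("g3", GenomicInterval("chr1", 11_000, 14_500), "-"),
        GeneModel("g4", GenomicInterval("chr1", 20_000, 21_000), "+"),
        GeneModel("g5", GenomicInterval("chr1", 25_000, 30_000), "-"),
    ]
    pos = np.sort(rng.choice(np.arange(1, 33_000), size=1500, replace=False))
    cov = rng.poisson(10, size=1500) + 1
    calls = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": pos,
            "strand": "+",
            "context": "CG",
            "methylated": rng.binomial(cov, 0.5),
            "coverage": cov,
        }
    )
    prof = metaplot(calls, genes, "CG", flank_bp=1000, body_bins=10, flank_bins=5)
    oracle = _oracle_metaplot(calls, genes, "CG", 1000, 10, 5)
    np.testing.assert_allclose(prof.values, oracle, rtol=1e-12, equal_nan=True)


def test_minus_strand_mirror_reproduces_plus_profile():
    size = 10_000
    plus_gene = GeneModel("g+", GenomicInterval("chr1", 3000, 5000), "+")
    rows = [("chr1", p, "+", "CG", (p * 13) % 7, 8) for p in range(2001, 6200, 17)]
    calls = make_calls(rows)
    # mirror the fixture: position p (1-based) -> size - p + 1, strand flipped
    mirrored = calls.copy()
    mirrored["pos"] = size - calls["pos"] + 1
    mirrored = mirrored.sort_values("pos").reset_index(drop=True)
    minus_gene = GeneModel("g-", GenomicInterval("chr1", size - 5000, size - 3000), "-")
    p_plus = metaplot(calls, [plus_gene], "CG", flank_bp=800, body_bins=8, flank_bins=4)
    p_minus = metaplot(mirrored, [minus_gene], "CG", flank_bp=800, body_bins=8, flank_bins=4)
    np.testing.assert_array_equal(p_plus.meth, p_minus.meth)
    np.testing.assert_array_equal(p_plus.cov, p_minus.cov)


def test_pooling_is_counts_not_mean_of_gene_ratios():
    """Weighted pooling equals count accumulation and deliberately differs
    from the mean of per-gene ratios at unequal coverage."""
    g1 = GeneModel("g1", GenomicInterval("chr1", 0, 100), "+")
    g2 = GeneModel("g2", GenomicInterval("chr1", 200, 300), "+")
    calls = make_calls(
        [("chr1", 50, "+", "CG", 90, 100), ("chr1", 250, "+", "CG", 0, 10)]
    )
    prof = metaplot(calls, [g1, g2], "CG", flank_bp=0, body_bins=1, flank_bins=1)
    pooled = prof.values[prof.upstream_bins]
    assert pooled == pytest.approx(90 / 110)
    assert pooled != pytest.approx((0.9 + 0.0) / 2)


def test_te_exclusion_drops_te_overlap_genes():
    genes = [GeneModel("g1", GenomicInterval("chr1", 0, 1000), "+"),
             GeneModel("g2", GenomicInterval("chr1", 2000, 3000), "+")]
    tes = [TEAnnotation(GenomicInterval("chr1", 400, 600), "I", "Gypsy")]
    calls = _uniform_calls(4000)
    all_p, free_p, frac = metaplot_excluding_te_genes(calls, genes, tes, "CG")
    assert frac == pytest.approx(0.5)
    assert free_p.n_features == 1
    # no TEs -> identical profiles
    a, b, frac0 = metaplot_excluding_te_genes(calls, genes, [], "CG")
    np.testing.assert_array_equal(a.cov, b.cov)
    assert frac0 == 0.0


# ---------------------------------------------------------------------------
# expression grouping
# ---------------------------------------------------------------------------

def test_expression_groups_partition_genes():
    fpkm = pd.Series({"a": 0.0, "b": 1.0, "c": 0.5, "d": 2.0, "e": 10.0, "f": 33.0})
    binary = group_by_expression(fpkm, "binary")
    assert {"b", "d", "e", "f"} == binary[0].gene_ids  # FPKM >= 1 is expressed
    clusters = group_by_expression(fpkm, "clusters")
    by_label = {g.label: g.gene_ids for g in clusters}
    assert by_label["Cluster1"] == {"a"}
    assert by_label["Cluster3"] == {"e"}          # FPKM = 10 resolves into Cluster3
    union = set().union(*(g.gene_ids for g in clusters))
    assert union == set(fpkm.index)
    sizes = sum(len(g.gene_ids) for g in clusters)
    assert sizes == len(fpkm)                     # pairwise disjoint
    with pytest.raises(ValueError):
        group_by_expression(pd.Series({"a": -1.0}), "binary")


def test_group_metaplots_match_individual_runs():
    genes = [GeneModel(f"g{i}", GenomicInterval("chr1", i * 3000, i * 3000 + 2000), "+")
             for i in range(1, 5)]
    calls = _uniform_calls(16_000)
    groups = group_by_expression(
        pd.Series({"g1": 0.0, "g2": 0.0, "g3": 5.0, "g4": 5.0}), "binary"
    )
    profs = group_metaplots(calls, genes, groups, "CG", flank_bp=500)
    solo = metaplot(calls, genes[2:], "CG", flank_bp=500)
    np.testing.assert_array_equal(profs["expressed"].cov, solo.cov)
    empty = group_metaplots(calls, genes, [group_by_expression(
        pd.Series({"zz": 3.0}), "binary")[0]], "CG")
    assert empty["expressed"].n_features == 0
    assert np.isnan(empty["expressed"].values).all()


# ---------------------------------------------------------------------------
# rank-sum machinery
# ---------------------------------------------------------------------------

def test_wilcoxon_matches_exact_enumeration_oracle():
    x = np.array([1.2, 3.4, 0.5, 7.1])
    y = np.array([2.2, 5.6, 8.3, 9.0])
    ranks = pd.Series(np.concatenate([x, y])).rank().to_numpy()
    n1 = len(x)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for idx in combinations(range(len(ranks)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        us.append(u)
    us = np.array(us)
    p_oracle = min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))
    assert wilcoxon_rank_sum(x, y) == pytest.approx(p_oracle, rel=1e-12)


def test_quartiles_sizes_and_direction(rng):
    genes = []
    fpkm = {}
    rows = []
    for i in range(40):
        start = 1000 + i * 2000
        g = GeneModel(f"g{i:02d}", GenomicInterval("chr1", start, start + 1000), "+")
        genes.append(g)
        level = i / 40
        expr = 100.0 * (1 - level) + rng.normal(0, 1e-6)  # strictly inverse coupling
        fpkm[g.gene_id] = max(expr, 0.0)
        for p in range(start + 1, start + 1000, 40):
            rows.append(("chr1", p, "+", "CHG", int(round(level * 50)), 50))
    res = quartile_expression_test(make_calls(rows), genes, pd.Series(fpkm),
                                   region="body", context="CHG")
    sizes = [len(v) for v in res["quartiles"].values()]
    assert max(sizes) - min(sizes) <= 1
    assert res["median_fpkm"]["Q4"] < res["median_fpkm"]["Q1"]
    assert res["pvalues"][("Q1", "Q4")] < 0.01
    with pytest.raises(ValueError, match="too few"):
        quartile_expression_test(make_calls(rows[:3]), genes[:1], pd.Series(fpkm))


def test_quartile_ties_broken_deterministically():
    genes = [GeneModel(f"g{i}", GenomicInterval("chr1", i * 2000, i * 2000 + 1000), "+")
             for i in range(1, 9)]
    rows = [("chr1", g.interval.start + 10, "+", "CG", 5, 10) for g in genes]
    fpkm = pd.Series({g.gene_id: 1.0 for g in genes})
    res1 = quartile_expression_test(make_calls(rows), genes, fpkm, context="CG")
    res2 = quartile_expression_test(make_calls(rows), genes, fpkm, context="CG")
    assert res1["quartiles"] == res2["quartiles"]
    flat = [g for q in res1["quartiles"].values() for g in q]
    assert flat == sorted(flat)  # all-tied levels fall back to gene id order


def test_expressed_vs_unexpressed_swap_symmetry():
    genes = [GeneModel(f"g{i}", GenomicInterval("chr1", i * 4000, i * 4000 + 1000), "+")
             for i in range(1, 11)]
    rows = []
    for i, g in enumerate(genes, 1):
        lvl = 40 if i <= 5 else 10
        for p in range(g.interval.start - 500, g.interval.start, 50):
            rows.append(("chr1", p + 1, "+", "CG", lvl, 100))
    calls = make_calls(rows)
    fpkm = pd.Series({g.gene_id: (0.0 if i <= 5 else 9.0) for i, g in enumerate(genes, 1)})
    groups = group_by_expression(fpkm, "binary")
    res = expressed_vs_unexpressed_test(calls, genes, groups, "upstream", "CG", 500)
    swapped = expressed_vs_unexpressed_test(calls, genes, groups[::-1], "upstream", "CG", 500)
    assert res["difference"] == pytest.approx(-swapped["difference"])
    assert res["p"] == pytest.approx(swapped["p"])
    assert res["means"]["expressed"] < res["means"]["unexpressed"]


def test_region_methylation_is_strand_aware():
    gplus = GeneModel("gp", GenomicInterval("chr1", 5000, 6000), "+")
    gminus = GeneModel("gm", GenomicInterval("chr1", 5000, 6000), "-")
    calls = make_calls([("chr1", 4501, "+", "CG", 8, 10), ("chr1", 6500, "+", "CG", 1, 10)])
    up_plus = region_methylation(calls, [gplus], "upstream", "CG", 1000)
    up_minus = region_methylation(calls, [gminus], "upstream", "CG", 1000)
    assert up_plus["gp"] == pytest.approx(0.8)
    assert up_minus["gm"] == pytest.approx(0.1)
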