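"""Tiling-window DMR calling: filters, Fisher test, classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plantmeth._stats import fisher_exact_two_sided
from plantmeth.calls import GeneModel, GenomicInterval, TEAnnotation
from plantmeth.dmr import (
    DMRConfig,
    call_dmrs,
    classify_features,
    dmr_gene_profile,
    genome_partition_fractions,
    paint_feature_classes,
    tile_and_count,
)
from plantmeth.dmr import test_bin as bin_exact_test  # alias: not a test case
from conftest import make_calls


def _paired_calls(sites):
    """(pos, ctx, meth_a, cov_a, meth_b, cov_b) -> two call frames."""
    a = make_calls([("chr1", p, "+", c, ma, ca) for p, c, ma, ca, mb, cb in sites])
    b = make_calls([("chr1", p, "+", c, mb, cb) for p, c, ma, ca, mb, cb in sites])
    return a, b


def test_low_coverage_sites_excluded_in_either_group():
    # "more than 3 reads" -> a site at coverage 3 in one group contributes nowhere
    sites = [
        (10, "CG", 2, 3, 5, 20),    # cov_a = 3 -> excluded
        (20, "CG", 2, 4, 5, 20),
        (30, "CG", 2, 10, 5, 20),
        (40, "CG", 2, 10, 5, 20),
    ]
    a, b = _paired_calls(sites)
    tiles = tile_and_count(a, b, DMRConfig(), "CG")
    assert tiles.iloc[0]["n_sites"] == 3
    assert tiles.iloc[0]["cov_a"] == 24


def test_bins_below_site_minimum_dropped():
    sites = [(10, "CG", 2, 10, 5, 20), (20, "CG", 2, 10, 5, 20)]
    a, b = _paired_calls(sites)
    assert len(tile_and_count(a, b, DMRConfig(), "CG")) == 0
    cfg = DMRConfig(min_sites_per_bin=2)
    assert len(tile_and_count(a, b, cfg, "CG")) == 1


def test_tile_counts_match_hand_tally():
    sites = [
        (5, "CG", 1, 10, 2, 8),
        (50, "CG", 4, 12, 0, 9),
        (99, "CG", 7, 7, 3, 11),
        (150, "CG", 2, 20, 2, 20),  # second bin, below min sites
    ]
    a, b = _paired_calls(sites)
    tiles = tile_and_count(a, b, DMRConfig(), "CG")
    assert len(tiles) == 1
    row = tiles.iloc[0]
    assert (row["start"], row["meth_a"], row["cov_a"], row["meth_b"], row["cov_b"],
            row["n_sites"]) == (0, 12, 29, 5, 28, 3)


def test_fisher_closed_form_and_identity():
    # [[10,0],[0,10]]: the two extreme tables of the hypergeometric support
    from math import comb

    assert bin_exact_test(10, 10, 0, 10) == pytest.approx(2 / comb(20, 10), rel=1e-12)
    assert bin_exact_test(5, 10, 5, 10) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        bin_exact_test(5, 0, 1, 10)


def test_fisher_matches_scipy_oracle(rng):
    a = rng.integers(0, 25, size=200)
    b = rng.integers(0, 25, size=200)
    c = rng.integers(0, 25, size=200)
    d = rng.integers(0, 25, size=200)
    mine = fisher_exact_two_sided(a, b, c, d)
    for i in range(200):
        _, p = stats.fisher_exact([[a[i], b[i]], [c[i], d[i]]])
        assert mine[i] == pytest.approx(p, rel=1e-9, abs=1e-12)


def test_fisher_matches_enumeration_oracle(rng):
    for _ in range(100):
        a, b, c, d = (int(x) for x in rng.integers(0, 30, size=4))
        K, n, N = a + c, a + b, a + b + c + d
        kmin, kmax = max(0, K - (c + d)), min(K, n)
        pmf = np.array([stats.hypergeom.pmf(k, N, K, n) for k in range(kmin, kmax + 1)])
        obs = stats.hypergeom.pmf(a, N, K, n)
        expected = pmf[pmf <= obs * (1 + 1e-7)].sum()
        got = float(fisher_exact_two_sided([a], [b], [c], [d])[0])
        assert got == pytest.approx(min(expected, 1.0), abs=1e-12)


def _synthetic_comparison(rng, n_bins=40, diff_bins=(3, 17), base=0.2, delta=0.6):
    rows_a, rows_b = [], []
    for b in range(n_bins):
        pa = base + (delta if b in diff_bins else 0.0)
        for s in range(4):
            pos = b * 100 + 10 + s * 20 + 1
            ca, cb = 60, 60
            rows_a.append(("chr1", pos, "+", "CG", rng.binomial(ca, pa), ca))
            rows_b.append(("chr1", pos, "+", "CG", rng.binomial(cb, base), cb))
    return make_calls(rows_a), make_calls(rows_b)


def test_call_dmrs_finds_planted_bins_and_directions(rng):
    a, b = _synthetic_comparison(rng)
    res = call_dmrs(a, b, DMRConfig(), "CG")
    assert set(res.dmrs["start"] // 100) == {3, 17}
    assert (res.dmrs["direction"] == "hyper").all()
    assert (res.dmrs["diff"].abs() > 0.4).all()     # audit: strict threshold
    assert (res.dmrs["q"] <= 0.05).all()


def test_swapping_groups_negates_diffs_and_keeps_p(rng):
    a, b = _synthetic_comparison(rng)
    res_ab = call_dmrs(a, b, DMRConfig(), "CG")
    res_ba = call_dmrs(b, a, DMRConfig(), "CG")
    merged = res_ab.tested.merge(res_ba.tested, on=["chrom", "start"], suffixes=("_ab", "_ba"))
    np.testing.assert_allclose(merged["diff_ab"], -merged["diff_ba"], atol=1e-12)
    np.testing.assert_allclose(merged["p_ab"], merged["p_ba"], rtol=1e-10)
    assert (res_ab.dmrs["direction"].to_numpy() == "hyper").all()
    assert (res_ba.dmrs["direction"].to_numpy() == "hypo").all()


def test_dmr_set_invariant_to_row_order(rng):
    a, b = _synthetic_comparison(rng)
    a_shuf = a.sample(frac=1, random_state=3).reset_index(drop=True)
    b_shuf = b.sample(frac=1, random_state=4).reset_index(drop=True)
    r1 = call_dmrs(a, b, DMRConfig(), "CG")
    r2 = call_dmrs(a_shuf, b_shuf, DMRConfig(), "CG")
    pd.testing.assert_frame_equal(r1.dmrs, r2.dmrs)


def test_null_comparison_calls_no_dmrs(rng):
    fractions = []
    for seed in range(3):
        r = np.random.default_rng(seed)
        rows_a, rows_b = [], []
        for b in range(200):
            p = 0.3
            for s in range(3):
                pos = b * 100 + 15 + s * 25 + 1
                rows_a.append(("chr1", pos, "+", "CG", r.binomial(60, p), 60))
                rows_b.append(("chr1", pos, "+", "CG", r.binomial(60, p), 60))
        res = call_dmrs(make_calls(rows_a), make_calls(rows_b), DMRConfig(), "CG")
        fractions.append(len(res.dmrs) / res.n_tested)
    assert np.mean(fractions) <= 0.01


def test_zero_tested_bins_errors():
    a = make_calls([("chr1", 10, "+", "CG", 1, 2)])
    with pytest.raises(ValueError, match="zero tested"):
        call_dmrs(a, a, DMRConfig(), "CG")


# ---------------------------------------------------------------------------
# feature classification
# ---------------------------------------------------------------------------

@pytest.fixture
def toy_annotation():
    sizes = {"chr1": 20_000}
    gene = GeneModel(
        "g1",
        GenomicInterval("chr1", 8000, 12_000),
        "+",
        [GenomicInterval("chr1", 8000, 9000), GenomicInterval("chr1", 11_000, 12_000)],
    )
    tes = [TEAnnotation(GenomicInterval("chr1", 9500, 10_000), "I", "Gypsy")]
    return sizes, [gene], tes


def test_midpoint_precedence(toy_annotation):
    sizes, genes, tes = toy_annotation
    dmrs = pd.DataFrame(
        {
            "chrom": ["chr1"] * 5,
            "start": [9700, 8200, 10_300, 7400, 100],
            "end": [9800, 8300, 10_400, 7500, 200],
            "direction": ["hyper"] * 5,
        }
    )
    out, fractions = classify_features(dmrs, genes, tes, sizes, flank_bp=2000)
    # TE inside an intron wins; exon; intron; upstream (500 bp 5' of TSS); intergenic
    assert out["feature_class"].tolist() == ["TE", "exon", "intron", "upstream", "intergenic"]
    assert sum(fractions.values()) == pytest.approx(1.0, abs=1e-9)


def test_partition_fractions_match_hand_accounting(toy_annotation):
    sizes, genes, tes = toy_annotation
    paint = paint_feature_classes(sizes, genes, tes, flank_bp=2000)
    fr = genome_partition_fractions(paint)
    total = 20_000
    assert fr["TE"] == pytest.approx(500 / total)
    assert fr["exon"] == pytest.approx(2000 / total)
    assert fr["intron"] == pytest.approx(1500 / total)   # 2000 bp minus the TE
    assert fr["upstream"] == pytest.approx(2000 / total)
    assert fr["downstream"] == pytest.approx(2000 / total)
    assert fr["intergenic"] == pytest.approx(12_000 / total)


def test_dmr_gene_profile_counts_and_locality(toy_annotation):
    _, genes, _ = toy_annotation
    empty = dmr_gene_profile(pd.DataFrame(columns=["chrom", "start", "end", "direction"]),
                             genes)
    assert (empty["hyper_count"] == 0).all() and (empty["hypo_count"] == 0).all()
    dmrs = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1"],
            "start": [6100, 6400],
            "end": [6200, 6500],
            "direction": ["hyper", "hypo"],
        }
    )
    prof = dmr_gene_profile(dmrs, genes, flank_bp=2000, body_bins=10, flank_bins=10)
    body = prof[prof["segment"] == "body"]
    assert body[["hyper_count", "hypo_count"]].to_numpy().sum() == 0
    up = prof[prof["segment"] == "up"]
    # midpoints 6150 and 6450 sit 1850/1550 bp 5' of the TSS -> bins 0 and 2
    assert up.iloc[0]["hyper_count"] == 1
    assert up.iloc[2]["hypo_count"] == 1
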