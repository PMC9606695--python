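"""Call-file IO, replicate merging, and weighted-level arithmetic."""

import itertools

import pandas as pd
import pytest

from plantmeth.calls import (
    CallFileError,
    GeneModel,
    GenomicInterval,
    MISSING,
    merge_replicates,
    read_calls,
    read_gene_annotations,
    read_te_annotations,
    TEAnnotation,
    weighted_level,
    write_calls,
    write_gene_gff3,
    write_te_bed,
)
from conftest import make_calls, random_calls


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def test_read_methratio_dialect(tmp_path):
    p = tmp_path / "calls.tsv"
    p.write_text("# chrom pos strand context meth cov\nchr1\t101\t+\tCG\t4\t10\n")
    df = read_calls(p, "methratio")
    assert df.iloc[0].tolist() == ["chr1", 101, "+", "CG", 4, 10]


def test_read_cx_dialect_sums_counts(tmp_path):
    p = tmp_path / "calls.tsv"
    p.write_text("chr1\t101\t+\t4\t6\tCG\tCGT\n")
    df = read_calls(p, "cx")
    row = df.iloc[0]
    assert (row["methylated"], row["coverage"]) == (4, 10)


@pytest.mark.parametrize(
    "line,match",
    [
        ("chr1\t101\t+\tCG\t12\t10\n", "exceeds coverage"),
        ("chr1\t101\t+\tCGG\t4\t10\n", "context"),
        ("chr1\t101\t*\tCG\t4\t10\n", "strand"),
        ("chr1\t101\t+\tCG\tfour\t10\n", "line 1"),
        ("chr1\t101\t+\tCG\t4\n", "line 1"),
    ],
)
def test_malformed_rows_name_the_line(tmp_path, line, match):
    p = tmp_path / "bad.tsv"
    p.write_text(line)
    with pytest.raises((CallFileError, ValueError), match=match):
        read_calls(p)


def test_zero_coverage_rows_dropped(tmp_path):
    p = tmp_path / "calls.tsv"
    p.write_text("chr1\t5\t+\tCG\t0\t0\nchr1\t9\t+\tCG\t1\t2\n")
    df = read_calls(p)
    assert df["pos"].tolist() == [9]


def test_round_trip_preserves_records(tmp_path, rng):
    calls = random_calls(rng).sort_values(["chrom", "pos"], kind="mergesort")
    calls = calls.reset_index(drop=True)
    path = tmp_path / "rt.tsv"
    write_calls(calls, path)
    back = read_calls(path)
    pd.testing.assert_frame_equal(back, calls)


# ---------------------------------------------------------------------------
# replicate merging
# ---------------------------------------------------------------------------

def test_merge_sums_counts_at_shared_site():
    a = make_calls([("chr1", 10, "+", "CG", 4, 10)])
    b = make_calls([("chr1", 10, "+", "CG", 1, 10)])
    merged = merge_replicates(a, b)
    assert merged.iloc[0][["methylated", "coverage"]].tolist() == [5, 20]


def test_merge_single_replicate_is_identity():
    a = make_calls([("chr1", 10, "+", "CG", 4, 10), ("chr1", 20, "-", "CHH", 0, 3)])
    pd.testing.assert_frame_equal(merge_replicates(a), a)


def test_merge_matches_brute_force_union_oracle(rng):
    """Sites present in only one replicate are carried through; shared sites
    sum — verified against a dict-accumulation oracle on a 20-site fixture."""
    a = random_calls(rng, n=20, span=200)
    b = a.sample(12, random_state=1).copy()
    b["pos"] = b["pos"] + 300  # disjoint block only in replicate 2
    expected = {}
    for df in (a, b):
        for r in df.itertuples():
            key = (r.chrom, r.pos, r.strand)
            m, c, ctx = expected.get(key, (0, 0, r.context))
            expected[key] = (m + r.methylated, c + r.coverage, ctx)
    merged = merge_replicates(a, b)
    assert len(merged) == len(expected)
    for r in merged.itertuples():
        m, c, ctx = expected[(r.chrom, r.pos, r.strand)]
        assert (r.methylated, r.coverage, r.context) == (m, c, ctx)


def test_merge_is_order_independent(rng):
    frames = [random_calls(rng, n=30, span=500) for _ in range(3)]
    reference = merge_replicates(*frames)
    for perm in itertools.permutations(frames):
        pd.testing.assert_frame_equal(merge_replicates(*perm), reference)
    # associativity: merging a merge equals merging all at once
    nested = merge_replicates(merge_replicates(frames[0], frames[1]), frames[2])
    pd.testing.assert_frame_equal(nested, reference)


def test_merge_conflicting_context_errors():
    a = make_calls([("chr1", 10, "+", "CG", 4, 10)])
    b = make_calls([("chr1", 10, "+", "CHG", 1, 10)])
    with pytest.raises(ValueError, match="conflicting context"):
        merge_replicates(a, b)


# ---------------------------------------------------------------------------
# weighted level
# ---------------------------------------------------------------------------

def test_weighted_level_single_site():
    calls = make_calls([("chr1", 10, "+", "CG", 4, 10)])
    assert weighted_level(calls) == pytest.approx(0.4)


def test_weighted_level_pools_reads_not_ratios():
    calls = make_calls(
        [("chr1", 10, "+", "CG", 5, 10), ("chr1", 20, "+", "CG", 0, 10)]
    )
    assert weighted_level(calls) == pytest.approx(0.25)


def test_weighted_level_zero_and_missing():
    calls = make_calls([("chr1", 10, "+", "CG", 0, 10)])
    assert weighted_level(calls) == 0.0
    assert weighted_level(calls, region=GenomicInterval("chr1", 100, 200)) is MISSING
    assert weighted_level(calls, context="CHH") is MISSING


def test_weighted_level_matches_per_site_accumulation(rng):
    calls = random_calls(rng, n=300, span=5000)
    region = GenomicInterval("chr1", 1000, 4000)
    for ctx in (None, "CG", "CHH"):
        meth = cov = 0
        for r in calls.itertuples():
            if 1000 <= r.pos - 1 < 4000 and r.coverage >= 3 and (
                ctx is None or r.context == ctx
            ):
                meth += r.methylated
                cov += r.coverage
        expected = meth / cov if cov else None
        got = weighted_level(calls, region, ctx, min_coverage=3)
        if expected is None:
            assert got is MISSING
        else:
            assert got == pytest.approx(expected)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def test_gff_coordinates_shift_to_zero_based(tmp_path):
    gff = tmp_path / "g.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr1\tsrc\tgene\t1\t100\t.\t+\t.\tID=g1\n"
    )
    genes = read_gene_annotations(gff)
    assert genes[0].interval == GenomicInterval("chr1", 0, 100)
    # gene without exon children gets one exon spanning the body
    assert genes[0].exons == [GenomicInterval("chr1", 0, 100)]


def test_exon_outside_gene_errors(tmp_path):
    gff = tmp_path / "g.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr1\tsrc\tgene\t10\t100\t.\t+\t.\tID=g1\n"
        "chr1\tsrc\texon\t150\t200\t.\t+\t.\tID=g1.e;Parent=g1\n"
    )
    with pytest.raises(ValueError, match="outside"):
        read_gene_annotations(gff)


def test_annotation_round_trip(tmp_path):
    genes = [
        GeneModel("g1", GenomicInterval("chr1", 100, 1100), "+",
                  [GenomicInterval("chr1", 100, 400), GenomicInterval("chr1", 700, 1100)]),
        GeneModel("g2", GenomicInterval("chr2", 0, 500), "-"),
    ]
    tes = [
        TEAnnotation(GenomicInterval("chr1", 450, 650), "I", "Gypsy"),
        TEAnnotation(GenomicInterval("chr2", 800, 1200), "II", "PIF-Harbinger"),
    ]
    write_gene_gff3(genes, tmp_path / "genes.gff3")
    write_te_bed(tes, tmp_path / "tes.bed")
    genes2 = read_gene_annotations(tmp_path / "genes.gff3")
    tes2 = read_te_annotations(tmp_path / "tes.bed")
    assert [(g.gene_id, g.interval, g.strand, g.exons) for g in genes2] == [
        (g.gene_id, g.interval, g.strand, g.exons) for g in genes
    ]
    assert [(t.interval, t.te_class, t.superfamily) for t in tes2] == [
        (t.interval, t.te_class, t.superfamily) for t in tes
    ]


def test_interval_and_te_invariants():
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 10, 10)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", -1, 5)
    with pytest.raises(ValueError, match="Class"):
        TEAnnotation(GenomicInterval("chr1", 0, 10), "II", "Gypsy")
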