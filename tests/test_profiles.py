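"""Windowed profiles, replicate correlation, context proportions, and
density/distance relations."""

import numpy as np
import pandas as pd
import pytest

from plantmeth.calls import GeneModel, GenomicInterval, TEAnnotation
from plantmeth.profiles import (
    WindowProfile,
    annotate_densities,
    context_proportions,
    density_correlation,
    replicate_correlation,
    te_distance_profile,
    te_gene_distances,
    window_methylation,
)
from conftest import make_calls, random_calls


def test_windows_tile_each_chromosome():
    sizes = {"chr1": 10_500, "chr2": 4_000}
    prof = window_methylation(make_calls([("chr1", 1, "+", "CG", 1, 2)]), sizes, 1000)
    table = prof.table
    for chrom, size in sizes.items():
        sub = table[table["chrom"] == chrom]
        assert (sub["end"] - sub["start"]).sum() == size  # conservation
        assert (sub["start"].to_numpy()[1:] == sub["end"].to_numpy()[:-1]).all()
    # trailing partial window retained
    assert table[table["chrom"] == "chr1"]["end"].max() == 10_500


def test_window_levels_match_site_loop_oracle(rng):
    calls = random_calls(rng, n=400, span=10_000)
    sizes = {"chr1": 10_000}
    prof = window_methylation(calls, sizes, 1000)
    for row in prof.table.itertuples():
        for ctx in ("CG", "CHG", "CHH"):
            meth = cov = 0
            for r in calls.itertuples():
                if row.start <= r.pos - 1 < row.end and r.context == ctx:
                    meth += r.methylated
                    cov += r.coverage
            got = getattr(row, f"level_{ctx}")
            if cov == 0:
                assert np.isnan(got)  # MISSING, never 0
            else:
                assert got == pytest.approx(meth / cov)


def test_uniform_methylome_gives_constant_windows():
    rows = [("chr1", p, "+", "CG", 3, 10) for p in range(1, 5001, 50)]
    prof = window_methylation(make_calls(rows), {"chr1": 5000}, 1000)
    levels = prof.table["level_CG"]
    assert np.allclose(levels.dropna(), 0.30)


def test_replicate_correlation_limits():
    rows = [("chr1", p, "+", "CG", (p * 7) % 11, 12) for p in range(1, 40_001, 40)]
    a = make_calls(rows)
    sizes = {"chr1": 40_000}
    assert replicate_correlation(a, a, sizes, 10_000) == pytest.approx(1.0)
    # three-window exact anti-correlation
    lv = [(1, 10), (2, 10), (3, 10)]
    a = make_calls([("chr1", 1 + i * 100, "+", "CG", m, c) for i, (m, c) in enumerate(lv)])
    b = make_calls([("chr1", 1 + i * 100, "+", "CG", m, c) for i, (m, c) in enumerate(lv[::-1])])
    r = replicate_correlation(a, b, {"chr1": 300}, 100)
    assert r == pytest.approx(-1.0)
    # symmetry
    assert replicate_correlation(b, a, {"chr1": 300}, 100) == pytest.approx(r)


def test_replicate_correlation_requires_three_windows():
    a = make_calls([("chr1", 1, "+", "CG", 1, 2)])
    with pytest.raises(ValueError, match="insufficient"):
        replicate_correlation(a, a, {"chr1": 1000}, 1000)


def test_context_proportions_symmetry_and_extremes():
    calls = make_calls(
        [
            ("chr1", 1, "+", "CG", 5, 10),
            ("chr1", 2, "+", "CHG", 5, 10),
            ("chr1", 3, "+", "CHH", 5, 10),
        ]
    )
    props = context_proportions(calls, site_call="any_read")
    assert props == {"CG": pytest.approx(1 / 3), "CHG": pytest.approx(1 / 3),
                     "CHH": pytest.approx(1 / 3)}
    only_chh = make_calls([("chr1", 1, "+", "CHH", 8, 10),
                           ("chr1", 2, "+", "CG", 0, 10)])
    assert context_proportions(only_chh, site_call="any_read")["CHH"] == 1.0


def test_context_proportions_sum_to_one(rng):
    calls = random_calls(rng, n=500)
    for mode in ("any_read", "binomial"):
        props = context_proportions(calls, site_call=mode)
        assert sum(props.values()) == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(ValueError):
        context_proportions(calls.iloc[:0])


def _profile_from(levels, densities):
    n = len(levels)
    table = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n) * 1000,
            "end": (np.arange(n) + 1) * 1000,
            "level_CG": levels,
            "gene_density": densities,
            "te_density": densities,
        }
    )
    return WindowProfile(1000, table)


def test_density_correlation_identity_and_closed_form():
    prof = _profile_from([0.1, 0.4, 0.2, 0.8, 0.5], [0.1, 0.4, 0.2, 0.8, 0.5])
    r, p = density_correlation(prof, "te", "CG")
    assert r == pytest.approx(1.0)
    # hand fixture vs the textbook formula
    x = np.array([0.0, 0.2, 0.1, 0.5, 0.3])
    y = np.array([0.15, 0.33, 0.21, 0.70, 0.42])
    prof = _profile_from(y, x)
    r, p = density_correlation(prof, "gene", "CG")
    rx = (x - x.mean()) / x.std()
    ry = (y - y.mean()) / y.std()
    assert r == pytest.approx(float((rx * ry).mean()), rel=1e-12)
    with pytest.raises(ValueError, match="zero variance"):
        density_correlation(_profile_from([0.2] * 5, [0.1, 0.2, 0.3, 0.4, 0.5]), "te", "CG")


def test_te_distances_definition():
    genes = [
        GeneModel("g1", GenomicInterval("chr1", 1000, 2000), "+"),
        GeneModel("g2", GenomicInterval("chr1", 5000, 6000), "+"),
    ]
    tes = [
        TEAnnotation(GenomicInterval("chr1", 1500, 1600), "I", "Gypsy"),   # overlaps
        TEAnnotation(GenomicInterval("chr1", 3000, 3200), "I", "Gypsy"),   # between
        TEAnnotation(GenomicInterval("chr1", 9000, 9100), "I", "Gypsy"),   # right of all
    ]
    d = te_gene_distances(tes, genes)
    assert d[0] == 0
    assert d[1] == min(3000 - 2000, 5000 - 3200)
    assert d[2] == 9000 - 6000


def test_te_distance_profile_decreases_with_planted_decay():
    genes = [GeneModel("g1", GenomicInterval("chr1", 0, 1000), "+")]
    tes, rows = [], []
    for i, gap in enumerate([100, 800, 1500, 3000, 6000]):
        start = 1000 + gap
        tes.append(TEAnnotation(GenomicInterval("chr1", start, start + 200), "I", "Gypsy"))
        level = 0.5 * np.exp(-gap / 2500)
        for p in range(start + 1, start + 200, 10):
            rows.append(("chr1", p, "+", "CHH", int(round(level * 100)), 100))
    prof = te_distance_profile(tes, genes, make_calls(rows),
                               distance_bins=(0, 500, 1000, 2000, 4000))
    means = prof["mean_level"].dropna().to_numpy()
    assert (np.diff(means) < 0).all()


def test_annotate_densities_te_bp_fraction():
    sizes = {"chr1": 4000}
    prof = window_methylation(make_calls([("chr1", 1, "+", "CG", 1, 2)]), sizes, 1000)
    tes = [TEAnnotation(GenomicInterval("chr1", 500, 2500), "I", "Gypsy")]
    genes = [GeneModel("g1", GenomicInterval("chr1", 3000, 3800), "+")]
    out = annotate_densities(prof, genes, tes).table
    assert out["te_density"].tolist() == pytest.approx([0.5, 1.0, 0.5, 0.0])
    assert out["gene_density"].tolist() == [0, 0, 0, 1]
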