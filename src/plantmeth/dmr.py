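"""Tiling-window differentially methylated region (DMR) calling.

The genome is divided into fixed-size tiles (100 bp by default); within a
tissue comparison, only cytosines covered by at least ``min_site_coverage``
reads in *both* groups contribute, and tiles with fewer than
``min_sites_per_bin`` qualifying sites are dropped.  Each retained tile is
tested with a two-sided Fisher's exact test on pooled methylated/unmethylated
counts, p-values are BH-FDR adjusted per context, and a tile is a DMR when its
q-value passes and the absolute level difference exceeds the context-specific
threshold (CG 0.4, CHG 0.2, CHH 0.1).  Each significant tile is one DMR
(no merging); ``hyper`` means higher methylation in group A, the left member
of the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import bh_adjust, fisher_exact_scalar, fisher_exact_two_sided
from .calls import GeneModel, TEAnnotation

#: Precedence used both for DMR midpoint classification and for the
#: genome-partition accounting (highest wins).
FEATURE_PRECEDENCE = ("TE", "exon", "intron", "upstream", "downstream", "intergenic")


@dataclass(frozen=True)
class DMRConfig:
    bin_size: int = 100
    min_site_coverage: int = 4  # "more than 3 reads" read literally as >= 4
    min_sites_per_bin: int = 3
    diff_thresholds: dict = field(
        default_factory=lambda: {"CG": 0.4, "CHG": 0.2, "CHH": 0.1}
    )
    q_threshold: float = 0.05

    def __post_init__(self):
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        for ctx, t in self.diff_thresholds.items():
            if not (0.0 < t < 1.0):
                raise ValueError(f"diff threshold for {ctx} outside (0,1)")
        if not (0.0 < self.q_threshold < 1.0):
            raise ValueError("q_threshold outside (0,1)")


def tile_and_count(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    config: DMRConfig = DMRConfig(),
    context: str = "CG",
) -> pd.DataFrame:
    """Pool per-tile counts for one context of a two-group comparison.

    Returns one row per retained tile: chrom, start (0-based), meth_a, cov_a,
    meth_b, cov_b, n_sites.  Inputs should already be replicate-merged per
    group.
    """
    a = calls_a[calls_a["context"] == context]
    b = calls_b[calls_b["context"] == context]
    merged = a.merge(
        b,
        on=["chrom", "pos", "strand"],
        suffixes=("_a", "_b"),
        how="inner",
        sort=False,
    )
    keep = (merged["coverage_a"] >= config.min_site_coverage) & (
        merged["coverage_b"] >= config.min_site_coverage
    )
    merged = merged[keep]
    if len(merged) == 0:
        return pd.DataFrame(
            columns=["chrom", "start", "meth_a", "cov_a", "meth_b", "cov_b", "n_sites"]
        )
    bin_start = ((merged["pos"].to_numpy() - 1) // config.bin_size) * config.bin_size
    agg = (
        merged.assign(start=bin_start)
        .groupby(["chrom", "start"], sort=True)
        .agg(
            meth_a=("methylated_a", "sum"),
            cov_a=("coverage_a", "sum"),
            meth_b=("methylated_b", "sum"),
            cov_b=("coverage_b", "sum"),
            n_sites=("pos", "size"),
        )
        .reset_index()
    )
    return agg[agg["n_sites"] >= config.min_sites_per_bin].reset_index(drop=True)


def test_bin(meth_a: int, cov_a: int, meth_b: int, cov_b: int) -> float:
    """Two-sided Fisher's exact p for one tile's pooled 2x2 count table
    [[meth_a, cov_a - meth_a], [meth_b, cov_b - meth_b]]."""
    if min(cov_a, cov_b) < 1:
        raise ValueError("coverage must be >= 1")
    if min(meth_a, meth_b) < 0 or meth_a > cov_a or meth_b > cov_b:
        raise ValueError("invalid counts")
    return fisher_exact_scalar(meth_a, cov_a - meth_a, meth_b, cov_b - meth_b)


@dataclass
class DMRResult:
    context: str
    dmrs: pd.DataFrame       # significant tiles only
    tested: pd.DataFrame     # all tested tiles with p and q
    config: DMRConfig

    @property
    def n_tested(self) -> int:
        return len(self.tested)


def call_dmrs(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    config: DMRConfig = DMRConfig(),
    context: str = "CG",
) -> DMRResult:
    """Call DMRs between group A (left member of the comparison) and group B.

    ``diff = level_a - level_b``; direction ``hyper`` iff diff > 0.
    """
    tiles = tile_and_count(calls_a, calls_b, config, context)
    if len(tiles) == 0:
        raise ValueError("zero tested bins")
    p = fisher_exact_two_sided(
        tiles["meth_a"].to_numpy(),
        (tiles["cov_a"] - tiles["meth_a"]).to_numpy(),
        tiles["meth_b"].to_numpy(),
        (tiles["cov_b"] - tiles["meth_b"]).to_numpy(),
    )
    q = bh_adjust(p)
    tiles = tiles.assign(
        end=tiles["start"] + config.bin_size,
        level_a=tiles["meth_a"] / tiles["cov_a"],
        level_b=tiles["meth_b"] / tiles["cov_b"],
        p=p,
        q=q,
    )
    tiles["diff"] = tiles["level_a"] - tiles["level_b"]
    threshold = config.diff_thresholds[context]
    sig = (tiles["q"] <= config.q_threshold) & (tiles["diff"].abs() > threshold)
    dmrs = tiles[sig].copy()
    dmrs["context"] = context
    dmrs["direction"] = np.where(dmrs["diff"] > 0, "hyper", "hypo")
    cols = [
        "chrom", "start", "end", "context", "level_a", "level_b",
        "diff", "p", "q", "direction", "n_sites",
    ]
    return DMRResult(context, dmrs[cols].reset_index(drop=True), tiles, config)


# ---------------------------------------------------------------------------
# genomic-feature classification
# ---------------------------------------------------------------------------

_CLASS_CODE = {name: i for i, name in enumerate(
    ("intergenic", "downstream", "upstream", "intron", "exon", "TE")
)}
_CODE_CLASS = {v: k for k, v in _CLASS_CODE.items()}


def paint_feature_classes(
    chrom_sizes: dict[str, int],
    genes: list[GeneModel],
    tes: list[TEAnnotation],
    flank_bp: int = 2000,
) -> dict[str, np.ndarray]:
    """Per-bp feature class arrays under the precedence
    TE > exon > intron > upstream > downstream > intergenic.

    Lower-precedence classes are painted first so higher ones overwrite them;
    the same arrays drive both DMR midpoint labels and the genome partition,
    which keeps the two mutually consistent by construction.
    """
    paint = {c: np.zeros(int(n), dtype=np.int8) for c, n in chrom_sizes.items()}

    def _set(chrom, lo, hi, code):
        arr = paint.get(chrom)
        if arr is None:
            return
        lo = max(0, lo)
        hi = min(len(arr), hi)
        if hi > lo:
            seg = arr[lo:hi]
            seg[seg < code] = code

    for g in genes:
        iv = g.interval
        if g.strand == "+":
            up = (iv.start - flank_bp, iv.start)
            down = (iv.end, iv.end + flank_bp)
        else:
            up = (iv.end, iv.end + flank_bp)
            down = (iv.start - flank_bp, iv.start)
        _set(iv.chrom, down[0], down[1], _CLASS_CODE["downstream"])
        _set(iv.chrom, up[0], up[1], _CLASS_CODE["upstream"])
        _set(iv.chrom, iv.start, iv.end, _CLASS_CODE["intron"])
        for ex in g.exons:
            _set(ex.chrom, ex.start, ex.end, _CLASS_CODE["exon"])
    for te in tes:
        _set(te.interval.chrom, te.interval.start, te.interval.end, _CLASS_CODE["TE"])
    return paint


def genome_partition_fractions(paint: dict[str, np.ndarray]) -> dict[str, float]:
    """bp fraction of the genome per feature class (sums to 1)."""
    counts = np.zeros(len(_CLASS_CODE), dtype=np.int64)
    total = 0
    for arr in paint.values():
        counts += np.bincount(arr, minlength=len(_CLASS_CODE))
        total += len(arr)
    return {_CODE_CLASS[i]: counts[i] / total for i in range(len(_CLASS_CODE))}


def classify_features(
    dmrs: pd.DataFrame,
    genes: list[GeneModel],
    tes: list[TEAnnotation],
    chrom_sizes: dict[str, int],
    flank_bp: int = 2000,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Label each DMR by the feature class of its midpoint and return the
    genome-wide bp fractions per class under the same precedence."""
    paint = paint_feature_classes(chrom_sizes, genes, tes, flank_bp)
    labels = []
    for row in dmrs.itertuples():
        arr = paint.get(row.chrom)
        mid = (int(row.start) + int(row.end)) // 2
        if arr is None or mid >= len(arr):
            labels.append("intergenic")
        else:
            labels.append(_CODE_CLASS[int(arr[mid])])
    out = dmrs.copy()
    out["feature_class"] = labels
    return out, genome_partition_fractions(paint)


def dmr_gene_profile(
    dmrs: pd.DataFrame,
    genes: list[GeneModel],
    flank_bp: int = 2000,
    body_bins: int = 20,
    flank_bins: int = 20,
) -> pd.DataFrame:
    """Hyper/hypo DMR density along the scaled gene body plus flanks.

    DMR midpoints are mapped into gene-scaled coordinates (flanks fixed-width,
    body length-normalized, minus-strand genes flipped); per bin, counts are
    normalized per gene and per kb of mean bin width.
    """
    nb = 2 * flank_bins + body_bins
    counts = {"hyper": np.zeros(nb), "hypo": np.zeros(nb)}
    if len(dmrs) == 0 or not genes:
        frame = _profile_frame(counts, flank_bins, body_bins)
        frame["hyper_density"] = 0.0
        frame["hypo_density"] = 0.0
        return frame
    mids = ((dmrs["start"].to_numpy() + dmrs["end"].to_numpy()) // 2).astype(np.int64)
    chroms = dmrs["chrom"].to_numpy()
    direction = dmrs["direction"].to_numpy()
    by_chrom = {}
    for c in np.unique(chroms):
        m = chroms == c
        order = np.argsort(mids[m], kind="mergesort")
        by_chrom[c] = (mids[m][order], direction[m][order])
    body_bp = 0.0
    for g in genes:
        iv = g.interval
        got = by_chrom.get(iv.chrom)
        body_bp += iv.length
        if got is None:
            continue
        pos, dirs = got
        lo = np.searchsorted(pos, iv.start - flank_bp)
        hi = np.searchsorted(pos, iv.end + flank_bp)
        for p, d in zip(pos[lo:hi], dirs[lo:hi]):
            if p < iv.start:
                k = (p - (iv.start - flank_bp)) * flank_bins // flank_bp
            elif p >= iv.end:
                k = flank_bins + body_bins + (p - iv.end) * flank_bins // flank_bp
            else:
                k = flank_bins + (p - iv.start) * body_bins // iv.length
            k = int(min(max(k, 0), nb - 1))
            if g.strand == "-":
                k = nb - 1 - k
            counts[d][k] += 1
    frame = _profile_frame(counts, flank_bins, body_bins)
    n_genes = len(genes)
    flank_width_kb = (flank_bp / flank_bins) / 1000.0
    mean_body_kb = (body_bp / n_genes / body_bins) / 1000.0
    widths = np.array(
        [flank_width_kb] * flank_bins + [mean_body_kb] * body_bins + [flank_width_kb] * flank_bins
    )
    widths = np.maximum(widths, 1e-12)
    frame["hyper_density"] = counts["hyper"] / (n_genes * widths)
    frame["hypo_density"] = counts["hypo"] / (n_genes * widths)
    return frame


def _profile_frame(counts, flank_bins, body_bins):
    nb = 2 * flank_bins + body_bins
    seg = (["up"] * flank_bins + ["body"] * body_bins + ["down"] * flank_bins)
    return pd.DataFrame(
        {
            "bin_index": np.arange(nb),
            "segment": seg,
            "hyper_count": counts["hyper"].astype(int),
            "hypo_count": counts["hypo"].astype(int),
        }
    )


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_dmr_tsv(dmrs: pd.DataFrame, path) -> None:
    """DMR TSV with 1-based inclusive coordinates."""
    out = dmrs.copy()
    out["start"] = out["start"] + 1
    out.rename(
        columns={"level_a": "level_A", "level_b": "level_B", "p": "pvalue", "q": "qvalue"}
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_dmr_bed(dmrs: pd.DataFrame, path) -> None:
    """BED6 export: name=context:direction, score = -10*log10(q) capped at 1000."""
    with open(path, "w") as fh:
        for row in dmrs.itertuples():
            q = max(row.q, 1e-300)
            score = min(1000, int(round(-10.0 * np.log10(q))))
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t"
                f"{row.context}:{row.direction}\t{score}\t.\n"
            )
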