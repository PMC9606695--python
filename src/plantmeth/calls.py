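"""Methylation call IO and core methylation arithmetic.

Whole-genome bisulfite sequencing reports, for every covered cytosine, how many
reads carried a methylated C (``methylated``) out of all reads covering the
site (``coverage``).  The weighted methylation level of any region is then
sum(methylated) / sum(coverage) over its cytosines — the mC/(mC + non-mC)
ratio — computed separately per sequence context (CG, CHG, CHH; H = A/T/C).

Conventions used throughout the package:

* call tables are pandas DataFrames with columns
  ``chrom, pos, strand, context, methylated, coverage`` (``pos`` 1-based);
* genomic intervals are 0-based half-open (:class:`GenomicInterval`);
* an uncovered region has level ``None`` (MISSING), never 0 — absence of
  evidence must not imitate hypomethylation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

CONTEXTS = ("CG", "CHG", "CHH")
STRANDS = ("+", "-")
CALL_COLUMNS = ["chrom", "pos", "strand", "context", "methylated", "coverage"]

#: Missing level sentinel (regions with no qualifying cytosine).
MISSING = None

#: TE superfamily -> class lookup (Class I: retrotransposons, Class II: DNA
#: transposons).  Unlisted superfamilies are accepted with the class given in
#: the annotation file.
SUPERFAMILY_CLASS = {
    "Gypsy": "I",
    "Copia": "I",
    "LINE": "I",
    "SINE": "I",
    "PIF-Harbinger": "II",
    "hAT": "II",
    "CACTA": "II",
    "Mutator": "II",
    "Tc1-Mariner": "II",
    "Helitron": "II",
}


class CallFileError(ValueError):
    """Raised for malformed methylation call files; names the offending line."""


class MethylationCall(NamedTuple):
    chrom: str
    pos: int
    strand: str
    context: str
    methylated: int
    coverage: int


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def expanded(self, flank: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, max(0, self.start - flank), self.end + flank)


@dataclass
class GeneModel:
    gene_id: str
    interval: GenomicInterval
    strand: str
    exons: list = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r} for {self.gene_id}")
        if not self.exons:
            self.exons = [self.interval]
        self.exons = sorted(self.exons, key=lambda e: e.start)
        prev_end = None
        for ex in self.exons:
            if not self.interval.contains(ex):
                raise ValueError(f"exon outside gene body for {self.gene_id}")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"overlapping exons for {self.gene_id}")
            prev_end = ex.end

    @property
    def length(self) -> int:
        """Sum of exon lengths (transcript length used for FPKM)."""
        return sum(e.length for e in self.exons)

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def introns(self) -> list:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.interval.chrom, a.end, b.start))
        return out


@dataclass
class TEAnnotation:
    interval: GenomicInterval
    te_class: str
    superfamily: str

    def __post_init__(self):
        if self.te_class not in ("I", "II"):
            raise ValueError(f"unknown TE class {self.te_class!r}")
        known = SUPERFAMILY_CLASS.get(self.superfamily)
        if known is not None and known != self.te_class:
            raise ValueError(
                f"superfamily {self.superfamily} is Class {known}, "
                f"annotation says Class {self.te_class}"
            )


# ---------------------------------------------------------------------------
# call-file IO
# ---------------------------------------------------------------------------

_DIALECT_COLUMNS = {
    "methratio": ["chrom", "pos", "strand", "context", "methylated", "coverage"],
    "cx": [
        "chrom",
        "pos",
        "strand",
        "count_methylated",
        "count_unmethylated",
        "context",
        "trinucleotide",
    ],
}


def _leading_comment_lines(path) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                n += 1
            else:
                break
    return n


def _fail_line(path, skip: int, names, converters) -> None:
    """Slow re-scan to name the first malformed line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= skip or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(names):
                raise CallFileError(
                    f"{path}: line {lineno}: expected {len(names)} fields, "
                    f"got {len(fields)}"
                )
            for name, value in zip(names, fields):
                conv = converters.get(name)
                if conv is None:
                    continue
                try:
                    conv(value)
                except Exception:
                    raise CallFileError(
                        f"{path}: line {lineno}: bad value {value!r} "
                        f"in column {name}"
                    ) from None
    raise CallFileError(f"{path}: malformed file")


def read_calls(path, dialect: str = "methratio") -> pd.DataFrame:
    """Read a per-cytosine methylation call table.

    ``methratio`` dialect: chrom, pos(1-based), strand, context, methylated,
    coverage.  ``cx`` dialect (Bismark CX report style): chrom, pos, strand,
    count_methylated, count_unmethylated, context, trinucleotide; counts are
    converted to (methylated, coverage = methylated + unmethylated).

    Rows with zero coverage are dropped (one record per *covered* cytosine);
    output is sorted by (chrom, pos).
    """
    if dialect not in _DIALECT_COLUMNS:
        raise ValueError(f"unknown dialect {dialect!r}")
    names = _DIALECT_COLUMNS[dialect]
    int_cols = [n for n in names if n in ("pos", "methylated", "coverage",
                                          "count_methylated", "count_unmethylated")]
    skip = _leading_comment_lines(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=names,
            skiprows=skip,
            comment="#",
            dtype={n: (np.int64 if n in int_cols else str) for n in names},
        )
    except (ValueError, pd.errors.ParserError):
        _fail_line(path, skip, names, {n: int for n in int_cols})
        raise  # unreachable

    if df.isna().any().any():
        _fail_line(path, skip, names, {n: int for n in int_cols})

    if dialect == "cx":
        df = df.assign(
            methylated=df["count_methylated"],
            coverage=df["count_methylated"] + df["count_unmethylated"],
        )

    offset = skip + 1  # data row i sits at physical line i + offset (approx.)
    bad = ~df["context"].isin(CONTEXTS)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise CallFileError(
            f"{path}: line {i + offset}: unknown context token "
            f"{df['context'].iloc[i]!r}"
        )
    bad = ~df["strand"].isin(STRANDS)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise CallFileError(
            f"{path}: line {i + offset}: unknown strand token "
            f"{df['strand'].iloc[i]!r}"
        )
    bad = (df["methylated"] > df["coverage"]) | (df["methylated"] < 0)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise CallFileError(
            f"{path}: line {i + offset}: methylated "
            f"{df['methylated'].iloc[i]} exceeds coverage "
            f"{df['coverage'].iloc[i]}"
        )
    bad = df["pos"] < 1
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise CallFileError(f"{path}: line {i + offset}: position < 1")

    df = df.loc[df["coverage"] > 0, CALL_COLUMNS]
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return df


def write_calls(calls: pd.DataFrame, path) -> None:
    """Write a call table in the methratio dialect (tab-separated, 1-based)."""
    calls[CALL_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def validate_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Check call-table invariants; returns the frame unchanged."""
    if not (calls["methylated"] <= calls["coverage"]).all():
        raise ValueError("methylated exceeds coverage")
    if not (calls["methylated"] >= 0).all():
        raise ValueError("negative methylated count")
    if not (calls["pos"] >= 1).all():
        raise ValueError("position < 1")
    if not calls["context"].isin(CONTEXTS).all():
        raise ValueError("unknown context token")
    return calls


# ---------------------------------------------------------------------------
# replicate merging and weighted levels
# ---------------------------------------------------------------------------

def merge_replicates(*call_sets: pd.DataFrame) -> pd.DataFrame:
    """Pool replicate call tables by summing counts per (chrom, pos, strand).

    Sites present in only one replicate are retained; a site annotated with
    different contexts across replicates is an error (the context is a property
    of the reference sequence, not of a library).
    """
    if not call_sets:
        raise ValueError("no call sets given")
    if len(call_sets) == 1:
        df = call_sets[0]
        return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    cat = pd.concat(call_sets, ignore_index=True)
    # integer site keys (chrom rank, pos, strand) for fast aggregation
    chrom_codes, chrom_uniques = pd.factorize(cat["chrom"])
    rank = np.argsort(np.argsort(chrom_uniques))  # appearance code -> sorted rank
    chrom_sorted = np.asarray(chrom_uniques)[np.argsort(chrom_uniques)]
    codes = rank[chrom_codes].astype(np.int64)
    pos = cat["pos"].to_numpy(dtype=np.int64)
    strand_minus = (cat["strand"].to_numpy() == "-").astype(np.int64)
    span = int(pos.max()) + 1
    key = (codes * span + pos) * 2 + strand_minus
    uniq, inv = np.unique(key, return_inverse=True)
    meth = np.bincount(inv, weights=cat["methylated"].to_numpy()).astype(np.int64)
    cov = np.bincount(inv, weights=cat["coverage"].to_numpy()).astype(np.int64)
    ctx_codes, ctx_uniques = pd.factorize(cat["context"])
    ctx_min = np.full(len(uniq), np.iinfo(np.int64).max)
    ctx_max = np.full(len(uniq), -1)
    np.minimum.at(ctx_min, inv, ctx_codes)
    np.maximum.at(ctx_max, inv, ctx_codes)
    if (ctx_min != ctx_max).any():
        j = int(np.flatnonzero(ctx_min != ctx_max)[0])
        k = int(uniq[j])
        site = (chrom_sorted[k // 2 // span], (k // 2) % span)
        raise ValueError(f"conflicting context at site {site}")
    first_row = np.full(len(uniq), len(cat))
    np.minimum.at(first_row, inv, np.arange(len(cat)))
    out = pd.DataFrame(
        {
            "chrom": chrom_sorted[(uniq // 2) // span],
            "pos": (uniq // 2) % span,
            "strand": np.where(uniq % 2 == 1, "-", "+"),
            "context": cat["context"].to_numpy()[first_row],
            "methylated": meth,
            "coverage": cov,
        }
    )
    # np.unique sorts keys, i.e. by (chrom rank, pos, strand) already
    return out[CALL_COLUMNS]


def region_mask(calls: pd.DataFrame, region: GenomicInterval) -> np.ndarray:
    """Boolean mask of calls whose cytosine lies inside a 0-based interval."""
    pos0 = calls["pos"].to_numpy() - 1
    return (
        (calls["chrom"].to_numpy() == region.chrom)
        & (pos0 >= region.start)
        & (pos0 < region.end)
    )


def weighted_level(
    calls: pd.DataFrame,
    region: GenomicInterval | None = None,
    context: str | None = None,
    min_coverage: int = 1,
):
    """Weighted methylation level over a region: sum(mC) / sum(coverage).

    Returns a float in [0, 1], or :data:`MISSING` (None) when no site
    qualifies.  ``context=None`` pools all three contexts.
    """
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    mask = calls["coverage"].to_numpy() >= min_coverage
    if context is not None:
        mask &= calls["context"].to_numpy() == context
    if region is not None:
        mask &= region_mask(calls, region)
    cov = int(calls["coverage"].to_numpy()[mask].sum())
    if cov == 0:
        return MISSING
    meth = int(calls["methylated"].to_numpy()[mask].sum())
    return meth / cov


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def _gene_from_gff(feature, exons) -> GeneModel:
    if feature.end < feature.start:
        raise ValueError(f"end < start in GFF feature {feature.id}")
    gid = feature.attributes.get("ID", [feature.id])[0]
    interval = GenomicInterval(feature.seqid, feature.start - 1, feature.end)
    exon_ivs = []
    for ex in exons:
        if ex.end < ex.start:
            raise ValueError(f"end < start in exon of {gid}")
        exon_ivs.append(GenomicInterval(ex.seqid, ex.start - 1, ex.end))
    if feature.strand not in STRANDS:
        raise ValueError(f"unknown strand token {feature.strand!r} in GFF")
    return GeneModel(gid, interval, feature.strand, exon_ivs)


def read_gene_annotations(gff_path) -> list[GeneModel]:
    """Read gene/exon models from GFF3 (1-based, inclusive) into 0-based
    half-open :class:`GeneModel` records; genes lacking exon children get a
    single exon spanning the gene body."""
    import gffutils

    db = gffutils.create_db(
        str(gff_path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = list(db.children(feat, featuretype="exon", order_by="start"))
        genes.append(_gene_from_gff(feat, exons))
    return genes


def read_te_annotations(te_path) -> list[TEAnnotation]:
    """Read TE annotations from BED6+1 (name=superfamily, column 7=class) or
    from GFF3 with ``superfamily``/``te_class`` attributes."""
    te_path = Path(te_path)
    if te_path.suffix.lower() in (".gff", ".gff3"):
        import gffutils

        db = gffutils.create_db(
            str(te_path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        out = []
        for feat in db.all_features(order_by=("seqid", "start")):
            sf = feat.attributes.get("superfamily", ["unknown"])[0]
            cls = feat.attributes.get("te_class", [None])[0]
            if cls is None:
                cls = SUPERFAMILY_CLASS.get(sf)
            if cls is None:
                raise ValueError(f"TE feature without class: {feat}")
            out.append(
                TEAnnotation(GenomicInterval(feat.seqid, feat.start - 1, feat.end), cls, sf)
            )
        return out
    df = pd.read_csv(
        te_path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "superfamily", "score", "strand", "te_class"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
        comment="#",
    )
    if (df["end"] < df["start"]).any():
        raise ValueError(f"{te_path}: end < start in TE record")
    return [
        TEAnnotation(GenomicInterval(r.chrom, int(r.start), int(r.end)), r.te_class, r.superfamily)
        for r in df.itertuples()
    ]


def read_annotations(gff_path, te_path):
    """Read gene models and TE annotations together."""
    return read_gene_annotations(gff_path), read_te_annotations(te_path)


def write_gene_gff3(genes: Sequence[GeneModel], path) -> None:
    """Write gene models as GFF3 (1-based inclusive; round-trips with
    :func:`read_gene_annotations`)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\tplantmeth\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, ex in enumerate(g.exons, 1):
                fh.write(
                    f"{ex.chrom}\tplantmeth\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


def write_te_bed(tes: Sequence[TEAnnotation], path) -> None:
    with open(path, "w") as fh:
        for te in tes:
            iv = te.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{te.superfamily}\t0\t+\t{te.te_class}\n"
            )


def chrom_sizes_from_calls(calls: pd.DataFrame) -> dict[str, int]:
    """Conservative chromosome sizes inferred from the largest observed
    position (used only when no genome table is supplied)."""
    return calls.groupby("chrom")["pos"].max().astype(int).to_dict()
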