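"""Synthetic multi-tissue methylome + transcriptome generator with known truth.

Emulates the statistical structure the analysis assumes, at a desk scale
(default: 2 chromosomes x 5 Mb) sized so the full pipeline runs in minutes on
one CPU:

* alternating gene-rich / TE-rich compartments at a 500-kb scale, so TE
  density correlates positively with CG/CHG methylation and negatively with
  gene density;
* three sequence contexts with distinct levels; CHH sites ~2.8x as numerous
  as CG+CHG combined; per-site methylation is bimodal (a site is either in a
  methylated state at a context-typical level, or unmethylated), which is what
  makes methylcytosine context shares and valley levels realistic;
* genic CHH slightly enriched over intergenic CHH; TE CHH decays with
  distance to the nearest gene;
* tissue-level global offsets ordering pith > rind > root > leaf;
* planted DMRs (per-context effect sizes, exact group levels overriding the
  background), planted DMVs (<1% everywhere), planted DEGs with configurable
  negative-binomial dispersion, and DMR-DEG coupling;
* expression-coupled methylation: gene body/flank methylation scales down
  with the gene's expression tier.

Everything is deterministic under a fixed seed: each stage and each
(tissue, replicate) methylome draws from its own fixed-derivation RNG stream,
so call order does not matter.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calls import (
    CALL_COLUMNS,
    CONTEXTS,
    GeneModel,
    GenomicInterval,
    TEAnnotation,
    write_gene_gff3,
    write_te_bed,
)

_COMP_INTERGENIC, _COMP_FLANK, _COMP_GENE, _COMP_TE = 0, 1, 2, 3
_COMP_NAMES = {0: "intergenic", 1: "flank", 2: "gene_body", 3: "TE"}

_SUPERFAMILY_POOL = (
    ("Gypsy", "I", 0.45),
    ("Copia", "I", 0.25),
    ("PIF-Harbinger", "II", 0.10),
    ("hAT", "II", 0.08),
    ("CACTA", "II", 0.07),
    ("Mutator", "II", 0.05),
)


@dataclass
class SimConfig:
    """Study conditions for the synthetic methylome/transcriptome.

    Defaults are the package's reference conditions; see docs/methods.md for
    the calibration rationale behind each value.
    """

    seed: int = 1
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 800
    n_tes: int = 1200
    te_fraction_target: float = 0.45
    te_in_gene_fraction: float = 0.423
    context_density: dict = field(
        default_factory=lambda: {"CG": 0.04, "CHG": 0.036, "CHH": 0.213}
    )
    tissues: tuple = ("leaf", "root", "rind", "pith")
    tissue_offsets: dict = field(
        default_factory=lambda: {"leaf": 1.00, "root": 1.03, "rind": 1.06, "pith": 1.09}
    )
    compartment_levels: dict = field(
        default_factory=lambda: {
            "TE": {"CG": 0.70, "CHG": 0.45, "CHH": 0.18},
            "gene_body": {"CG": 0.25, "CHG": 0.06, "CHH": 0.05},
            "flank": {"CG": 0.18, "CHG": 0.07, "CHH": 0.05},
            "intergenic": {"CG": 0.35, "CHG": 0.20, "CHH": 0.04},
        }
    )
    state_levels: dict = field(
        default_factory=lambda: {"CG": 0.90, "CHG": 0.65, "CHH": 0.20}
    )
    flank_bp: int = 2000
    # planted DMRs: length in bp (aligned to 100-bp tiles), per-context level
    # difference between the affected tissue and all others, and the midpoint
    # the two group levels straddle
    n_planted_dmrs: int = 300
    dmr_length: int = 300
    dmr_effects: dict = field(
        default_factory=lambda: {"CG": 0.8, "CHG": 0.4, "CHH": 0.2}
    )
    dmr_centers: dict = field(
        default_factory=lambda: {"CG": 0.5, "CHG": 0.35, "CHH": 0.2}
    )
    dmr_affected_tissue: str = "root"
    dmr_near_gene_frac: float = 0.5
    # planted DMVs
    n_planted_dmvs: int = 60
    dmv_length: int = 6000
    dmv_level: float = 0.003
    dmv_gene_frac: float = 0.5
    dmv_tf_odds: float = 3.0
    tf_fraction: float = 0.10
    # sequencing
    coverage_mean: float = 30.0
    coverage_model: str = "poisson"  # or "nb"
    nb_size: float = 10.0
    n_replicates: int = 2
    # TE CHH distance decay (multiplier floor + exp decay with gene distance)
    chh_distance_tau: float = 2000.0
    chh_distance_floor: float = 0.4
    # expression
    n_degs: int = 120
    deg_fold: float = 8.0
    deg_tissue: str = "root"
    nb_dispersion: float = 0.05
    dmr_deg_odds: float = 3.0
    expr_coupling_strength: float = 0.8
    tier_probs: tuple = (0.35, 0.20, 0.20, 0.25)
    library_size: float = 5e6
    library_size_jitter: float = 0.10

    @property
    def genome_size(self) -> int:
        return self.n_chroms * self.chrom_length

    @property
    def chrom_sizes(self) -> dict:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}

    def __post_init__(self):
        for d in (self.context_density, self.dmr_effects, self.dmr_centers):
            if set(d) != set(CONTEXTS):
                raise ValueError("per-context dicts must cover CG/CHG/CHH")
        for t in self.tissues:
            if t not in self.tissue_offsets:
                raise ValueError(f"no offset for tissue {t}")


@dataclass
class SimTruth:
    dmrs: pd.DataFrame            # chrom,start,end,context,direction,level_affected,level_other
    dmvs: list
    degs: pd.DataFrame            # gene_id, fold, direction, tissue
    gene_tiers: pd.Series         # 0..3 per gene (expression cluster index)
    target_fpkm: pd.Series
    tf_genes: set
    clip_fraction: float = 0.0


def _rng(config: SimConfig, *stream) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, *stream)))


class _Occupancy:
    """Sorted non-overlapping interval registry per chromosome."""

    def __init__(self):
        self._starts: dict[str, list] = {}
        self._ends: dict[str, list] = {}

    def fits(self, chrom, start, end, margin=0) -> bool:
        starts = self._starts.get(chrom, [])
        ends = self._ends.get(chrom, [])
        i = bisect_right(starts, start)
        if i > 0 and ends[i - 1] + margin > start:
            return False
        if i < len(starts) and end + margin > starts[i]:
            return False
        return True

    def add(self, chrom, start, end):
        starts = self._starts.setdefault(chrom, [])
        ends = self._ends.setdefault(chrom, [])
        i = bisect_right(starts, start)
        starts.insert(i, start)
        ends.insert(i, end)


@dataclass
class SimGenome:
    chrom_sizes: dict
    genes: list
    tes: list
    sites: pd.DataFrame                     # chrom,pos(1-based),strand,context
    block_size: int
    het_weights: dict                       # chrom -> per-block heterochromatin weight

    @property
    def gene_index(self) -> dict:
        return {g.gene_id: g for g in self.genes}


def _make_gene(rng, gene_id, chrom, start, length, strand, intron_len=None):
    end = start + length
    iv = GenomicInterval(chrom, start, end)
    if intron_len is not None and length >= intron_len + 400:
        left = (length - intron_len) // 2
        exons = [
            GenomicInterval(chrom, start, start + left),
            GenomicInterval(chrom, start + left + intron_len, end),
        ]
        return GeneModel(gene_id, iv, strand, exons)
    n_ex = int(rng.integers(1, 5))
    if n_ex == 1 or length < 60 * (2 * n_ex - 1):
        return GeneModel(gene_id, iv, strand, [iv])
    cuts = np.sort(rng.choice(np.arange(30, length - 30), 2 * (n_ex - 1), replace=False))
    bounds = np.concatenate([[0], cuts, [length]])
    exons = []
    ok = True
    for k in range(0, len(bounds) - 1, 2):
        lo, hi = int(bounds[k]), int(bounds[k + 1])
        if hi - lo < 20:
            ok = False
            break
        exons.append(GenomicInterval(chrom, start + lo, start + hi))
    if not ok:
        return GeneModel(gene_id, iv, strand, [iv])
    return GeneModel(gene_id, iv, strand, exons)


def generate_genome(config: SimConfig) -> SimGenome:
    """Lay out chromosomes, compartments, genes, TEs and cytosine sites."""
    rng = _rng(config, 0)
    block = 500_000
    chroms = sorted(config.chrom_sizes)
    het = {
        c: rng.uniform(0.15, 0.85, size=int(np.ceil(config.chrom_sizes[c] / block)))
        for c in chroms
    }

    def _pick_position(length, weight_fn, tries=400):
        for _ in range(tries):
            chrom = chroms[int(rng.integers(len(chroms)))]
            w = weight_fn(het[chrom])
            b = int(rng.choice(len(w), p=w / w.sum()))
            lo = b * block
            hi = min((b + 1) * block, config.chrom_sizes[chrom]) - length
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            yield chrom, start

    gene_occ = _Occupancy()
    genes = []
    n_host = int(round(config.te_in_gene_fraction * config.n_genes))
    host_te_lengths = rng.integers(300, 1200, size=n_host)
    for i in range(config.n_genes):
        hosted = i < n_host
        if hosted:
            intron = int(host_te_lengths[i]) + 200
            length = intron + int(rng.integers(800, 3000))
        else:
            intron = None
            length = int(np.clip(rng.lognormal(np.log(2200), 0.45), 800, 8000))
        strand = "+" if rng.random() < 0.5 else "-"
        placed = False
        for chrom, start in _pick_position(length, lambda h: 1.0 - h, tries=800):
            if gene_occ.fits(chrom, start, start + length, margin=300):
                gene_occ.add(chrom, start, start + length)
                genes.append(
                    _make_gene(rng, f"gene{i + 1:05d}", chrom, start, length, strand, intron)
                )
                placed = True
                break
        if not placed:
            raise RuntimeError("gene placement failed after bounded retries")

    # TEs: intronic ones inside host genes, the rest in TE-rich blocks
    te_occ = _Occupancy()
    tes = []
    sf_names = [s[0] for s in _SUPERFAMILY_POOL]
    sf_class = {s[0]: s[1] for s in _SUPERFAMILY_POOL}
    sf_probs = np.array([s[2] for s in _SUPERFAMILY_POOL])
    sf_probs = sf_probs / sf_probs.sum()

    def _superfamily():
        return sf_names[int(rng.choice(len(sf_names), p=sf_probs))]

    intronic_bp = 0
    for i in range(min(n_host, len(genes), config.n_tes)):
        g = genes[i]
        introns = g.introns
        if not introns:
            continue
        intron = max(introns, key=lambda iv: iv.length)
        te_len = int(host_te_lengths[i])
        if intron.length < te_len + 2:
            te_len = max(50, intron.length - 2)
        start = intron.start + (intron.length - te_len) // 2
        sf = _superfamily()
        tes.append(
            TEAnnotation(GenomicInterval(intron.chrom, start, start + te_len),
                         sf_class[sf], sf)
        )
        te_occ.add(intron.chrom, start, start + te_len)
        intronic_bp += te_len

    n_free = config.n_tes - len(tes)
    if n_free > 0:
        target_bp = max(config.te_fraction_target * config.genome_size - intronic_bp, 0)
        mean_len = max(target_bp / n_free, 300)
        sigma = 0.8
        lengths = np.clip(
            rng.lognormal(np.log(mean_len) - sigma**2 / 2, sigma, size=n_free),
            200, 30_000,
        ).astype(int)
        for L in lengths:
            L = int(L)
            # adaptively halve a TE that cannot fit anywhere (late placements
            # in a crowded genome); skip entirely below the minimum length
            while L >= 200:
                placed = False
                for chrom, start in _pick_position(L, lambda h: h, tries=200):
                    if gene_occ.fits(chrom, start, start + L, margin=50) and te_occ.fits(
                        chrom, start, start + L, margin=20
                    ):
                        te_occ.add(chrom, start, start + L)
                        sf = _superfamily()
                        tes.append(
                            TEAnnotation(GenomicInterval(chrom, start, start + L),
                                         sf_class[sf], sf)
                        )
                        placed = True
                        break
                if placed:
                    break
                L //= 2

    # cytosine sites: sample distinct (position, strand) slots per chromosome
    densities = config.context_density
    total_density = sum(densities.values())
    frames = []
    for ci, chrom in enumerate(chroms):
        size = config.chrom_sizes[chrom]
        srng = _rng(config, 1, ci)
        n_total = int(round(total_density * size))
        slots = srng.choice(2 * size, size=n_total, replace=False)
        n_per = {
            ctx: int(round(densities[ctx] / total_density * n_total))
            for ctx in CONTEXTS
        }
        # adjust rounding drift on the most numerous context
        n_per["CHH"] += n_total - sum(n_per.values())
        ctx_col = np.empty(n_total, dtype=object)
        off = 0
        for ctx in CONTEXTS:
            ctx_col[off : off + n_per[ctx]] = ctx
            off += n_per[ctx]
        pos0 = slots // 2
        strand = np.where(slots % 2 == 0, "+", "-")
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos0 + 1,
                    "strand": strand,
                    "context": ctx_col,
                }
            )
        )
    sites = pd.concat(frames, ignore_index=True)
    sites = sites.sort_values(
        ["chrom", "pos", "strand"], kind="mergesort"
    ).reset_index(drop=True)
    return SimGenome(dict(config.chrom_sizes), genes, tes, sites, block, het)


# ---------------------------------------------------------------------------
# truth planting
# ---------------------------------------------------------------------------

def _plant_features(config: SimConfig, genome: SimGenome) -> tuple[pd.DataFrame, list, set]:
    """Choose planted DMR intervals, DMV intervals, and TF gene ids."""
    rng = _rng(config, 2)
    occ = _Occupancy()
    chroms = sorted(genome.chrom_sizes)
    genes = genome.genes
    n_genes = len(genes)
    tf_ids = set(
        np.array([g.gene_id for g in genes])[
            rng.choice(n_genes, size=int(round(config.tf_fraction * n_genes)), replace=False)
        ]
    ) if n_genes else set()

    # --- DMVs (1-kb aligned) ---
    dmvs: list[GenomicInterval] = []
    if config.n_planted_dmvs and n_genes:
        # gene + 1-kb flanks must fit with 1-kb slack for bin-aligned rounding
        short_genes = [g for g in genes
                       if g.interval.length + 2000 <= config.dmv_length - 1000]
        weights = np.array(
            [config.dmv_tf_odds if g.gene_id in tf_ids else 1.0 for g in short_genes]
        )
        n_on_gene = int(round(config.dmv_gene_frac * config.n_planted_dmvs))
        order = (
            rng.choice(len(short_genes), size=min(n_on_gene * 3, len(short_genes)),
                       replace=False, p=weights / weights.sum())
            if short_genes else np.array([], dtype=int)
        )
        placed = 0
        for j in order:
            if placed >= n_on_gene:
                break
            g = short_genes[int(j)]
            mid = g.interval.midpoint
            # round to the nearest 1-kb boundary so the gene stays centered
            start = max(0, ((mid - config.dmv_length // 2 + 500) // 1000) * 1000)
            end = start + config.dmv_length
            if end > genome.chrom_sizes[g.interval.chrom]:
                continue
            if occ.fits(g.interval.chrom, start, end, margin=2000):
                occ.add(g.interval.chrom, start, end)
                dmvs.append(GenomicInterval(g.interval.chrom, start, end))
                placed += 1
        attempts = 0
        while len(dmvs) < config.n_planted_dmvs and attempts < 20_000:
            attempts += 1
            chrom = chroms[int(rng.integers(len(chroms)))]
            nbins = genome.chrom_sizes[chrom] // 1000 - config.dmv_length // 1000
            if nbins <= 0:
                continue
            start = int(rng.integers(0, nbins)) * 1000
            end = start + config.dmv_length
            if occ.fits(chrom, start, end, margin=2000):
                occ.add(chrom, start, end)
                dmvs.append(GenomicInterval(chrom, start, end))
        if len(dmvs) < config.n_planted_dmvs:
            raise RuntimeError(
                "DMV placement failed after bounded retries: genome too small "
                f"for {config.n_planted_dmvs} valleys of {config.dmv_length} bp"
            )

    # --- DMRs (100-bp aligned) ---
    rows = []
    if config.n_planted_dmrs:
        per_ctx = config.n_planted_dmrs // len(CONTEXTS)
        gene_starts = {}
        for g in genes:
            gene_starts.setdefault(g.interval.chrom, []).append(
                (g.interval.start, g.interval.end)
            )
        gene_arr = {
            c: (np.array([s for s, _ in sorted(v)]),
                np.maximum.accumulate(np.array([e for _, e in sorted(v)])))
            for c, v in gene_starts.items()
        }

        def _near_gene_start():
            g = genes[int(rng.integers(n_genes))]
            tss = g.interval.start if g.strand == "+" else g.interval.end
            if g.strand == "+":
                lo = tss - config.flank_bp
                hi = tss - config.dmr_length
            else:
                lo = tss + 100
                hi = tss + config.flank_bp - config.dmr_length
            if hi <= lo:
                return None
            start = (int(rng.integers(lo, hi)) // 100) * 100
            return g.interval.chrom, max(0, start)

        def _intergenic_start():
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = (int(rng.integers(0, genome.chrom_sizes[chrom] - config.dmr_length))
                     // 100) * 100
            got = gene_arr.get(chrom)
            if got is not None:
                s, e = got
                j = np.searchsorted(s, start + config.dmr_length + 2500)
                if j > 0 and e[j - 1] + 2500 > start:
                    return None
            return chrom, start

        for ctx in CONTEXTS:
            n_near = int(round(config.dmr_near_gene_frac * per_ctx))
            made = 0
            attempts = 0
            while made < per_ctx and attempts < 20_000:
                attempts += 1
                near = made < n_near
                got = _near_gene_start() if near else _intergenic_start()
                if got is None:
                    continue
                chrom, start = got
                end = start + config.dmr_length
                if start < 0 or end > genome.chrom_sizes[chrom]:
                    continue
                if not occ.fits(chrom, start, end, margin=500):
                    continue
                occ.add(chrom, start, end)
                direction = "hyper" if made % 2 == 0 else "hypo"
                eff = config.dmr_effects[ctx]
                center = config.dmr_centers[ctx]
                hi_lvl, lo_lvl = center + eff / 2, center - eff / 2
                rows.append(
                    {
                        "chrom": chrom,
                        "start": start,
                        "end": end,
                        "context": ctx,
                        "direction": direction,
                        "level_affected": hi_lvl if direction == "hyper" else lo_lvl,
                        "level_other": lo_lvl if direction == "hyper" else hi_lvl,
                        "near_gene": near,
                    }
                )
                made += 1
            if made < per_ctx:
                raise RuntimeError("DMR placement failed after bounded retries")
    dmr_df = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "context", "direction",
                 "level_affected", "level_other", "near_gene"],
    )
    return dmr_df, dmvs, tf_ids


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------

class SimStudy:
    """A generated study: genome, planted truth, expression matrix, and
    on-demand per-(tissue, replicate) methylomes."""

    def __init__(self, config: SimConfig):
        self.config = config
        self.genome = generate_genome(config)
        dmr_df, dmvs, tf_ids = _plant_features(config, self.genome)
        self.counts, self.sample_sheet, degs, tiers, target_fpkm = simulate_expression(
            self.genome, config, dmr_df
        )
        self.truth = SimTruth(dmr_df, dmvs, degs, tiers, target_fpkm, tf_ids)
        self._site_cache: dict = {}
        self._base_levels: np.ndarray | None = None

    # -- site-level truth ---------------------------------------------------

    def _compartments(self):
        """Per-site compartment code, owning-gene tier multiplier, and TE CHH
        decay multiplier (all aligned with genome.sites)."""
        if "comp" in self._site_cache:
            return self._site_cache["comp"]
        cfg = self.config
        genome = self.genome
        paint = {c: np.zeros(n, dtype=np.int8) for c, n in genome.chrom_sizes.items()}
        gene_of = {c: np.full(n, -1, dtype=np.int32) for c, n in genome.chrom_sizes.items()}
        te_of = {c: np.full(n, -1, dtype=np.int32) for c, n in genome.chrom_sizes.items()}
        for gi, g in enumerate(genome.genes):
            iv = g.interval
            arr = paint[iv.chrom]
            lo = max(0, iv.start - cfg.flank_bp)
            hi = min(len(arr), iv.end + cfg.flank_bp)
            seg = arr[lo:hi]
            seg[seg < _COMP_FLANK] = _COMP_FLANK
            arr[iv.start : iv.end] = np.maximum(arr[iv.start : iv.end], _COMP_GENE)
            gene_of[iv.chrom][lo:hi] = gi
        from .profiles import te_gene_distances

        te_dist = te_gene_distances(genome.tes, genome.genes) if genome.genes else None
        for ti, te in enumerate(genome.tes):
            iv = te.interval
            paint[iv.chrom][iv.start : iv.end] = _COMP_TE
            te_of[iv.chrom][iv.start : iv.end] = ti
        sites = genome.sites
        comp = np.empty(len(sites), dtype=np.int8)
        gidx = np.empty(len(sites), dtype=np.int32)
        tidx = np.empty(len(sites), dtype=np.int32)
        for chrom, grp in sites.groupby("chrom", sort=False):
            p0 = grp["pos"].to_numpy() - 1
            comp[grp.index] = paint[chrom][p0]
            gidx[grp.index] = gene_of[chrom][p0]
            tidx[grp.index] = te_of[chrom][p0]
        if te_dist is not None and len(genome.tes):
            decay = cfg.chh_distance_floor + (1.0 - cfg.chh_distance_floor) * np.exp(
                -np.minimum(te_dist, 1e12) / cfg.chh_distance_tau
            )
        else:
            decay = np.ones(max(len(genome.tes), 1))
        self._site_cache["comp"] = (comp, gidx, tidx, decay)
        return self._site_cache["comp"]

    def base_site_levels(self) -> np.ndarray:
        """Tissue-independent per-site base level (methylated-state draw times
        context state level, with compartment, TE-distance and expression-tier
        structure)."""
        if self._base_levels is not None:
            return self._base_levels
        cfg = self.config
        sites = self.genome.sites
        comp, gidx, tidx, te_decay = self._compartments()
        ctx_arr = sites["context"].to_numpy()
        mean_level = np.empty(len(sites))
        state_level = np.empty(len(sites))
        for ctx in CONTEXTS:
            m = ctx_arr == ctx
            state_level[m] = cfg.state_levels[ctx]
            for code, name in _COMP_NAMES.items():
                mm = m & (comp == code)
                mean_level[mm] = cfg.compartment_levels[name][ctx]
            # TE CHH decays with distance to the nearest gene
            if ctx == "CHH" and len(self.genome.tes):
                mm = m & (comp == _COMP_TE)
                mean_level[mm] *= te_decay[tidx[mm]]
        # expression coupling: body/flank methylation scales down with tier
        if cfg.expr_coupling_strength > 0 and len(self.genome.genes):
            tiers = self.truth.gene_tiers.to_numpy()
            in_gene = (gidx >= 0) & ((comp == _COMP_FLANK) | (comp == _COMP_GENE))
            mult = 1.0 - cfg.expr_coupling_strength * tiers[gidx[in_gene]] / 3.0
            mean_level[in_gene] *= mult
        pi = np.clip(mean_level / state_level, 0.0, 1.0)
        state = _rng(cfg, 3).random(len(sites)) < pi
        self._base_levels = state * state_level
        return self._base_levels

    def _site_lookup(self):
        """Per-chromosome (row range, sorted pos0) for fast interval slicing."""
        if "lookup" in self._site_cache:
            return self._site_cache["lookup"]
        sites = self.genome.sites
        pos0 = sites["pos"].to_numpy(dtype=np.int64) - 1
        chrom_arr = sites["chrom"].to_numpy()
        slices = {}
        lo = 0
        for chrom, grp in sites.groupby("chrom", sort=False):
            hi = lo + len(grp)
            slices[str(chrom)] = (lo, hi)
            lo = hi
        self._site_cache["lookup"] = (slices, pos0, sites["context"].to_numpy())
        return self._site_cache["lookup"]

    def site_levels(self, tissue: str) -> np.ndarray:
        """True per-site methylation level for a tissue (with planted DMR/DMV
        overrides applied)."""
        cached = self._site_cache.get(("levels", tissue))
        if cached is not None:
            return cached
        cfg = self.config
        base = self.base_site_levels()
        raw = base * cfg.tissue_offsets[tissue]
        clipped = int((raw > 1.0).sum())
        if clipped:
            self.truth.clip_fraction = clipped / len(base)
        level = np.clip(raw, 0.0, 1.0)
        slices, pos0, ctx_arr = self._site_lookup()

        def _rows(chrom, start, end):
            got = slices.get(chrom)
            if got is None:
                return 0, 0
            lo, hi = got
            a = lo + np.searchsorted(pos0[lo:hi], start)
            b = lo + np.searchsorted(pos0[lo:hi], end)
            return a, b

        for iv in self.truth.dmvs:
            a, b = _rows(iv.chrom, iv.start, iv.end)
            level[a:b] = cfg.dmv_level
        for row in self.truth.dmrs.itertuples():
            a, b = _rows(row.chrom, row.start, row.end)
            m = ctx_arr[a:b] == row.context
            level[a:b][m] = (
                row.level_affected if tissue == cfg.dmr_affected_tissue else row.level_other
            )
        self._site_cache[("levels", tissue)] = level
        return level

    # -- observed methylomes ------------------------------------------------

    def methylome(self, tissue: str, replicate: int, noiseless: bool = False) -> pd.DataFrame:
        """Observed call table for one tissue replicate (replicates are
        independent draws from the same per-tissue truth)."""
        cfg = self.config
        level = self.site_levels(tissue)
        sites = self.genome.sites
        n = len(sites)
        if noiseless:
            cov = np.full(n, max(int(round(cfg.coverage_mean)), 1), dtype=np.int64)
            meth = np.rint(cov * level).astype(np.int64)
        else:
            t_idx = list(cfg.tissues).index(tissue)
            rng = _rng(cfg, 10, t_idx, replicate)
            if cfg.coverage_model == "poisson":
                cov = rng.poisson(cfg.coverage_mean, size=n)
            elif cfg.coverage_model == "nb":
                p = cfg.nb_size / (cfg.nb_size + cfg.coverage_mean)
                cov = rng.negative_binomial(cfg.nb_size, p, size=n)
            else:
                raise ValueError(f"unknown coverage model {cfg.coverage_model!r}")
            meth = rng.binomial(cov, level)
        out = sites.copy()
        out["methylated"] = meth
        out["coverage"] = cov
        out = out[out["coverage"] > 0].reset_index(drop=True)
        return out[CALL_COLUMNS]

    def merged_methylome(self, tissue: str, noiseless: bool = False) -> pd.DataFrame:
        """Replicate-pooled call table for one tissue.

        Replicates share the genome's site list, so pooling is a direct
        count sum (equivalent to :func:`plantmeth.calls.merge_replicates`)."""
        cfg = self.config
        sites = self.genome.sites
        n = len(sites)
        meth = np.zeros(n, dtype=np.int64)
        cov = np.zeros(n, dtype=np.int64)
        level = self.site_levels(tissue)
        for rep in range(1, cfg.n_replicates + 1):
            if noiseless:
                c = np.full(n, max(int(round(cfg.coverage_mean)), 1), dtype=np.int64)
                m = np.rint(c * level).astype(np.int64)
            else:
                t_idx = list(cfg.tissues).index(tissue)
                rng = _rng(cfg, 10, t_idx, rep)
                if cfg.coverage_model == "poisson":
                    c = rng.poisson(cfg.coverage_mean, size=n)
                elif cfg.coverage_model == "nb":
                    p = cfg.nb_size / (cfg.nb_size + cfg.coverage_mean)
                    c = rng.negative_binomial(cfg.nb_size, p, size=n)
                else:
                    raise ValueError(f"unknown coverage model {cfg.coverage_model!r}")
                m = rng.binomial(c, level)
            meth += m
            cov += c
        out = sites.copy()
        out["methylated"] = meth
        out["coverage"] = cov
        out = out[out["coverage"] > 0].reset_index(drop=True)
        return out[CALL_COLUMNS]


def simulate_study(config: SimConfig | None = None) -> SimStudy:
    return SimStudy(config or SimConfig())


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _target_fpkm(rng, tiers: np.ndarray) -> np.ndarray:
    f = np.zeros(len(tiers))
    t1 = tiers == 1
    f[t1] = 10 ** rng.uniform(np.log10(0.3), np.log10(2.0), size=int(t1.sum()))
    t2 = tiers == 2
    f[t2] = 10 ** rng.uniform(np.log10(2.0), np.log10(10.0), size=int(t2.sum()))
    t3 = tiers == 3
    f[t3] = np.minimum(10 ** (1.0 + np.abs(rng.normal(0, 0.45, size=int(t3.sum())))), 300.0)
    return f


def simulate_expression(
    genome: SimGenome, config: SimConfig, dmr_truth: pd.DataFrame
):
    """Negative-binomial count matrix with planted DEGs coupled to planted
    DMRs.

    Returns (counts, sample_sheet, deg_truth, gene_tiers, target_fpkm).
    """
    rng = _rng(config, 4)
    genes = genome.genes
    gene_ids = [g.gene_id for g in genes]
    n = len(genes)
    tiers = rng.choice(4, size=n, p=np.asarray(config.tier_probs))
    fpkm = _target_fpkm(rng, tiers)
    lengths = np.array([g.length for g in genes], dtype=float)

    # DMR-overlapping genes (body +/- flank) get boosted DEG odds
    from .integrate import dmr_gene_overlap

    dmr_genes = (
        dmr_gene_overlap(dmr_truth, genes, config.flank_bp)
        if len(dmr_truth)
        else set()
    )
    eligible = np.flatnonzero(tiers >= 2)
    n_degs = min(config.n_degs, len(eligible))
    deg_rows = []
    deg_idx = np.array([], dtype=int)
    if n_degs and config.deg_fold > 1.0:
        w = np.array(
            [config.dmr_deg_odds if gene_ids[i] in dmr_genes else 1.0 for i in eligible]
        )
        deg_idx = eligible[
            rng.choice(len(eligible), size=n_degs, replace=False, p=w / w.sum())
        ]
        for k, gi in enumerate(deg_idx):
            deg_rows.append(
                {
                    "gene_id": gene_ids[gi],
                    "fold": config.deg_fold,
                    "direction": "up" if k % 2 == 0 else "down",
                    "tissue": config.deg_tissue,
                }
            )
    deg_truth = pd.DataFrame(deg_rows, columns=["gene_id", "fold", "direction", "tissue"])

    base_mean = fpkm * lengths * config.library_size / 1e9
    samples = []
    data = {}
    lib_sizes = {}
    for t_idx, tissue in enumerate(config.tissues):
        mean_t = base_mean.copy()
        for row in deg_truth.itertuples():
            gi = gene_ids.index(row.gene_id)
            if tissue == row.tissue:
                mean_t[gi] = (
                    mean_t[gi] * row.fold if row.direction == "up" else mean_t[gi] / row.fold
                )
        for rep in range(1, config.n_replicates + 1):
            srng = _rng(config, 5, t_idx, rep)
            u = 1.0 + config.library_size_jitter * (2 * srng.random() - 1.0)
            mu = mean_t * u
            if config.nb_dispersion > 0:
                size = 1.0 / config.nb_dispersion
                counts = srng.negative_binomial(size, size / (size + np.maximum(mu, 1e-12)))
                counts[mu <= 0] = 0
            else:
                counts = srng.poisson(mu)
            name = f"{tissue}_r{rep}"
            data[name] = counts
            lib_sizes[name] = int(round(config.library_size * u))
            samples.append({"sample": name, "tissue": tissue, "replicate": rep,
                            "library_size": lib_sizes[name]})
    counts_df = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))
    sheet = pd.DataFrame(samples)
    return (
        counts_df,
        sheet,
        deg_truth,
        pd.Series(tiers, index=gene_ids, name="tier"),
        pd.Series(fpkm, index=gene_ids, name="target_fpkm"),
    )


# ---------------------------------------------------------------------------
# study serialization (the formats the pipeline consumes)
# ---------------------------------------------------------------------------

def default_term_map(study: SimStudy) -> pd.DataFrame:
    """Flat gene -> term table: generic terms plus a transcription-factor term
    on TF genes and a sucrose-metabolism term on a deterministic subset."""
    rng = _rng(study.config, 6)
    rows = []
    generic = [f"TERM{k:03d}" for k in range(1, 21)]
    for g in study.genome.genes:
        for t in rng.choice(generic, size=int(rng.integers(1, 4)), replace=False):
            rows.append({"gene_id": g.gene_id, "term_id": t, "term_name": t.lower()})
        if g.gene_id in study.truth.tf_genes:
            rows.append({"gene_id": g.gene_id, "term_id": "TF",
                         "term_name": "transcription factor activity"})
        if rng.random() < 0.08:
            rows.append({"gene_id": g.gene_id, "term_id": "SUCROSE",
                         "term_name": "sucrose metabolism"})
    return pd.DataFrame(rows)


def write_study(study: SimStudy, outdir, noiseless: bool = False) -> dict:
    """Write the full study to disk in the formats the pipeline consumes.

    Returns a manifest dict mapping logical names to paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = study.config
    manifest = {}

    sizes = pd.DataFrame(
        sorted(cfg.chrom_sizes.items()), columns=["chrom", "size"]
    )
    sizes.to_csv(outdir / "genome.tsv", sep="\t", index=False)
    manifest["genome"] = outdir / "genome.tsv"

    write_gene_gff3(study.genome.genes, outdir / "genes.gff3")
    manifest["genes"] = outdir / "genes.gff3"
    write_te_bed(study.genome.tes, outdir / "tes.bed")
    manifest["tes"] = outdir / "tes.bed"

    for tissue in cfg.tissues:
        for rep in range(1, cfg.n_replicates + 1):
            path = outdir / f"calls_{tissue}_r{rep}.tsv"
            calls = study.methylome(tissue, rep, noiseless=noiseless)
            calls.to_csv(path, sep="\t", header=False, index=False)
            manifest[f"calls_{tissue}_r{rep}"] = path

    study.counts.reset_index().to_csv(outdir / "counts.tsv", sep="\t", index=False)
    manifest["counts"] = outdir / "counts.tsv"
    study.sample_sheet.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    manifest["samples"] = outdir / "samples.tsv"

    with open(outdir / "tf_genes.txt", "w") as fh:
        for gid in sorted(study.truth.tf_genes):
            fh.write(gid + "\n")
    manifest["tf_genes"] = outdir / "tf_genes.txt"

    default_term_map(study).to_csv(outdir / "term_map.tsv", sep="\t", index=False)
    manifest["term_map"] = outdir / "term_map.tsv"

    truth = study.truth
    truth.dmrs.to_csv(outdir / "dmr_truth.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(iv.chrom, iv.start, iv.end) for iv in truth.dmvs],
        columns=["chrom", "start", "end"],
    ).to_csv(outdir / "dmv_truth.tsv", sep="\t", index=False)
    truth.degs.to_csv(outdir / "deg_truth.tsv", sep="\t", index=False)
    manifest["dmr_truth"] = outdir / "dmr_truth.tsv"
    manifest["dmv_truth"] = outdir / "dmv_truth.tsv"
    manifest["deg_truth"] = outdir / "deg_truth.tsv"
    return manifest
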