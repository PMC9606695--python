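# Methods

This note documents the statistical model behind each stage of `plantmeth`,
the defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions that affect results.

## Methylation model and conventions

Whole-genome bisulfite sequencing observes, for each cytosine, a pair
(mC reads, total reads). The *weighted methylation level* of any region is

    level = sum(mC) / sum(coverage)

over the region's cytosines, computed per sequence context (CG, CHG, CHH;
H = A/T/C). Pooling counts before ratioing weights each cytosine by its
coverage; it is deliberately not the mean of per-site or per-gene ratios,
which is unstable at low coverage. Regions with no qualifying cytosine are
MISSING (`None`/NaN), never 0 — an uncovered bin must not imitate
hypomethylation, which matters most for valley detection.

Internal coordinates are 0-based half-open; all text outputs are 1-based
inclusive, matching the call-file convention. Context assignments are taken
from the input file and trusted; symmetric-CG strand collapsing is *not*
performed (the per-cytosine ratio definition does not require it, and
collapsing would silently change coverage filters). Replicates are pooled by
summing counts per site; a site with inconsistent context across replicates is
an error because context is a property of the reference sequence.

## Windowed profiles

Genome overviews use non-overlapping tiling windows (default 500 kb; the
trailing partial window is kept so window lengths always sum to the chromosome
length). Replicate reproducibility is the Pearson correlation of 100-kb-window
levels, excluding windows missing in either replicate. Gene density is a count
per window (genes assigned by midpoint); TE density is the TE-bp fraction of
the window. Density–methylation relations use Pearson correlation with the
two-sided t-transform p-value.

"Methylcytosine" for context-proportion summaries is decided per site by a
one-sided binomial test of mC reads against the bisulfite
non-conversion/sequencing error rate (default 0.005) with BH-FDR < 0.05;
an `any_read` mode is kept for sensitivity analysis. The binomial rule is the
standard call in the field when no explicit definition is given.

TE-to-gene distance profiles assign each TE the minimum gap to any gene
(0 when overlapping) and average per-TE body CHH levels within distance bins
(default edges 0, 0.5 k, 1 k, 2 k, 4 k, 8 k, ∞ — roughly log-spaced around
gene-proximal scales).

## Metaplots

Each feature body is mapped onto `body_bins` equal-width bins (length
normalization) with fixed-width flanks split into `flank_bins`; minus-strand
features are flipped so bins run 5′→3′. Defaults: 2 kb flanks, 20 + 20 + 20
bins — the convention in the maize/soybean methylome literature. Bins pool
(mC, coverage) counts across features and ratio at the end.

A cytosine is treated as a 1-bp interval; when a feature body is shorter than
the bin count the site's scaled span covers several bins and its counts are
distributed by fractional overlap. Overlaps are computed in integer units
(position × bin count against bin edge × body length), so the weights are
exact rationals and a mirrored minus-strand fixture reproduces a plus-strand
profile bit for bit. Short features therefore contribute smoothly instead of
erroring.

Expression groupings: binary (expressed FPKM ≥ 1 vs unexpressed < 1) and the
four FPKM clusters (0; (0,2]; (2,10]; >10). The printed sources disagree on
whether FPKM = 10 belongs to Cluster3 or Cluster4; we resolve 10.0 into
Cluster3 (the "≤ 10" reading) and note the boundary is configurable in the
code. Methylation quartiles rank genes by a region's weighted level (ties
broken deterministically by gene id, quartile sizes differing by at most 1)
and compare FPKM between quartile pairs by the two-sided Wilcoxon rank-sum
test — exact null enumeration when both samples are ≤ 20 without ties, normal
approximation with continuity correction otherwise. The "upstream" region is
the 2-kb 5′ flank by default; a promoter window (−2000..−200 from the TSS) is
exposed as an option.

## DMR calling

Tiles of 100 bp; a cytosine contributes only if covered by ≥ 4 reads
("more than 3") in *both* groups — symmetric filtering avoids composition
bias between groups; tiles with < 3 qualifying sites are dropped (the common
tiling default; configurable). Each retained tile is tested with a two-sided
Fisher's exact test on the pooled 2×2 table
[[mC_A, other_A], [mC_B, other_B]]; p-values are BH-adjusted per context, and
a tile is a DMR iff q ≤ 0.05 and |level_A − level_B| exceeds the context
threshold (CG 0.4, CHG 0.2, CHH 0.1). Each significant tile is one DMR — no
merging across tiles. `hyper` means higher methylation in group A, the left
member of the comparison (e.g. root in "root vs leaf").

The Fisher test is implemented in-repo, vectorized over tiles via log-gamma
hypergeometric pmfs with the standard relative gate (1 + 1e-7) for tail ties;
tests verify it against both `scipy.stats.fisher_exact` and exhaustive
enumeration to 1e-12. Fisher + BH was chosen over a logistic-regression tile
test because it is deterministic, assumption-light at pooled counts, and
oracle-verifiable.

DMR feature classification paints the genome at base-pair resolution under the
precedence TE > exon > intron > upstream > downstream > intergenic (flanks
2 kb) and labels each DMR by its midpoint's class. The same painted array
yields the genome partition fractions, so the labels and the partition are
consistent by construction and the fractions sum to 1 exactly. The painting
approach is O(genome) memory (1 byte/bp), appropriate for the desk-scale
genomes this package targets.

## DMV detection

1-kb tiling bins; a bin qualifies for a tissue iff all three contexts have
≥ 5 pooled reads and weighted level strictly < 5%. The read floor is our
addition (unstated in the sources): it prevents a 0/1-read context from
qualifying a bin spuriously. MISSING contexts disqualify. Bins qualifying in
*every* tissue are intersected, and adjacent or overlapping bins merged into
maximal runs (book-ended 1-kb tiles never strictly overlap, so "merge
overlapping" is read as merging contiguous runs; merging is idempotent and
equals an interval-union oracle). DMV genes: the gene body expanded by 1 kb
must lie entirely within a merged valley ("located in"; an any-overlap mode
is available). TF enrichment among DMV genes uses a 1-df chi-squared test
without continuity correction, falling back to Fisher's exact test when an
expected cell is below 1. A shared-valley percentage has no single natural
denominator, so the summary reports it against every candidate (each tissue's
count and the non-redundant count).

## Expression and differential expression

FPKM = count · 10⁹ / (transcript length · mapped-read total); per-tissue FPKM
averages replicates. Library sizes are an explicit input (sample sheet column
`library_size`); the column-sum fallback is only appropriate when the counts
matrix covers the whole transcriptome.

The DE stage is a self-contained negative-binomial Wald test:

1. median-of-ratios size factors (geometric-mean reference over genes with
   all-positive counts);
2. gene-wise method-of-moments dispersion from pooled within-group variances
   of normalized counts, shrunk 50/50 in log space toward a log-linear
   mean–dispersion trend. The trend is fitted to *signed* MoM bin means
   (negative bin means clamp to the 1e-8 floor), so on Poisson-like data the
   trend collapses and the Wald variance reduces to the Poisson term — the
   NB p-values then agree with a two-proportion z-test (a tested invariant);
3. Wald z on log2 of normalized group means (pseudocount 0.5 to avoid
   infinities), with Var(K/s) = μ/s + α μ² propagated by the delta method;
4. BH-FDR; a DEG requires q < 0.05 *and* |log2FC| ≥ 2 (the 4-fold rule),
   applied to the unshrunk fold estimate.

All-zero genes are flagged and skipped. This stage honors the thresholds of
interest exactly while remaining fully testable; it does not reproduce any
particular external DE engine.

## Integration

A gene is DMR-associated if any DMR overlaps its body ± 2-kb flanks (the same
flank as DMR classification). DEG × DMR-overlap association is a 2×2
chi-squared test (Fisher fallback when an expected cell < 5), reporting the
odds ratio (Haldane 0.5 correction only when a cell is zero) and the
proportion of DEGs carrying a DMR. Term enrichment is a one-sided
hypergeometric over a *flat* gene→terms map with BH-FDR; ontology hierarchies
and term propagation are deliberately out of scope (pre-propagated maps can be
supplied).

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, at a
scale (default 2 chromosomes × 5 Mb, 800 genes, 1,200 TEs, ~2.9 M cytosines,
4 tissues × 2 replicates at 30× Poisson coverage) chosen so the full pipeline
runs in minutes on one CPU.

Structure emulated:

* **Compartments.** 500-kb blocks carry a heterochromatin weight; TEs are
  placed preferentially in TE-rich blocks (target TE fraction 0.45) and genes
  in gene-rich blocks, which induces the negative gene–TE density correlation
  and the positive TE-density–mCG/mCHG correlations at the 500-kb window
  scale. 42.3% of genes host an intronic TE.
* **Sites and contexts.** Cytosine sites are sampled without positional
  collisions at densities CG 0.04, CHG 0.036, CHH 0.213 per bp, preserving
  CHH ≈ 2.8 × (CG + CHG). Densities are lower than a real plant genome —
  they are the knob that sets runtime — but keep ≥ ~4 CG sites per 100-bp
  tile so tile-level statistics behave like the real regime.
* **Bimodal site methylation.** Each site is either in a methylated state at
  a context-typical level (CG 0.90, CHG 0.65, CHH 0.20) or unmethylated; the
  state probability is compartment mean / state level. This reproduces both
  realistic weighted levels and a CHH share of binomially called
  methylcytosines near 70% (TE CHH mean 0.18; the share was calibrated
  analytically from the density × state-probability × detection-probability
  product).
* **Tissue offsets** multiply all base levels (leaf 1.00, root 1.03,
  rind 1.06, pith 1.09), giving the strict global ordering
  leaf < root < rind < pith. Offsets were chosen so that offset-induced
  between-tissue differences stay several noise SDs below every DMR diff
  threshold at the simulated coverage: at ~240 pooled reads per tile and
  group, the largest offset-induced CHG difference (~0.012 on a 0.4-level
  TE tile) sits ≈ 4 SD below the 0.2 threshold, so planted-DMR precision is
  measurable against truth.
* **Planted DMRs** are 300 bp (three tiles), tile-aligned, with exact group
  levels straddling a context-specific midpoint at twice the calling
  threshold (CG 0.9/0.1, CHG 0.55/0.15, CHH 0.3/0.1); the affected tissue
  (default root) gets one side, all other tissues the other. Three tiles
  rather than one because at ~4 CG sites per tile the probability that a
  single tile holds < 3 sites (and is untestable) is ~0.24 — a Poisson
  bin-occupancy fact, not a caller property; with three tiles the probability
  that no tile is testable is ~0.014. Half the DMRs are placed in gene
  upstream flanks (for DMR–DEG coupling), half in intergenic space away from
  genes.
* **Planted DMVs** are 6-kb, 1-kb-aligned, all-context level 0.003
  everywhere (< 1% in every tissue after offsets); half are centered on a
  short gene so valley-gene assignment has targets, with TF genes
  over-represented 3× among hosts. Expression-coupled hypomethylation can
  create additional genuine valleys around highly expressed genes — as in
  real genomes — so planted valleys are a subset of, not identical to, the
  detected set.
* **Expression.** Gene expression tiers (probabilities 0.35/0.20/0.20/0.25
  for FPKM 0, (0,2], (2,10], >10) set negative-binomial count means through
  the FPKM identity at a configured mapped-read total (5 × 10⁶ per sample,
  ±10% per-sample jitter). DEGs (default 120; 8-fold, dispersion 0.05) are
  planted in tier ≥ 2 genes of one tissue, sampled with 3× odds for genes
  whose flanks carry a planted DMR (the DMR–DEG coupling). Methylation of a
  gene's body and flanks is scaled by 1 − 0.8 · tier/3, producing the
  TSS-hypomethylation-with-expression ordering across FPKM clusters.
* **TE CHH distance decay.** TE-body CHH levels are multiplied by
  0.4 + 0.6 · exp(−d/2 kb), d = distance to the nearest gene, giving the
  monotone distance trend.

Determinism: every stage and every (tissue, replicate) methylome draws from
its own `SeedSequence`-derived stream, so results are identical across call
orders and platforms; observed coverage is Poisson(30) (negative-binomial
optional, size 10) and mC reads are Binomial(coverage, true level).
Replicates are independent draws from the same per-tissue truth, which makes
the 100-kb replicate correlation > 0.95 a property of the regime rather than
an assertion.

What the generator does **not** emulate — and hence what passing tests do not
show about real data: no sequence-level realism (no FASTA, no real context
spacing or CpG islands), no bisulfite conversion failure beyond the binomial
error knob, no mapping bias or coverage dips, no strand asymmetries, no
between-replicate biological variation in methylation (replicates share
truth, so replicate correlations are optimistic), no isoform structure, no
batch effects, and planted effects are piecewise-constant rather than
tapering. Recovery results on this generator validate the *machinery*
(binning, filtering, testing, bookkeeping), not the biological effect sizes.

## Problem sizes used in validation

The validation suite uses the default 2 × 5 Mb study for DMR recovery,
replicate correlation and the end-to-end run; a 2 × 2 Mb, 500-gene study for
the expression–methylation direction properties; a 2 × 5 Mb, 2,000-gene,
3-replicate study for DEG recovery and DMR–DEG association; the DMR null is
evaluated on 1,000 tiles × 20 seeds; valley recovery uses a noiseless
100-kb fixture with exact-ratio calls. The uniform-metaplot flatness check
uses exact-ratio calls (methylated = 0.4 × coverage), for which flatness is
deterministic; with binomially sampled calls the maximum of ~60 per-bin
z-scores exceeds 3 in a sizeable fraction of draws, so a sampled fixture
cannot support a deterministic every-bin 3-SE assertion — the sampled fixture
is retained for the strand-mirror identity, which is exact.

## Known limitations

* Fisher's exact test on pooled counts ignores between-replicate biological
  dispersion; with truly dispersed replicates it is anticonservative.
  Beta-binomial and smoothing-based callers are out of scope by design.
* Single-tile DMRs are not merged; consumers wanting regions should merge
  downstream.
* The DE stage's MoM-with-trend dispersion is serviceable for ≥ 2 replicates
  and planted-effect validation, not a replacement for mature DE engines on
  real data.
* Feature painting allocates 1 byte/bp per chromosome; genomes much beyond
  10⁸ bp per chromosome would need an interval-based classifier instead.
* The genome-partition fractions and valley genome-fraction depend strongly
  on the synthetic layout; they are bookkeeping checks, not biological
  estimates.
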