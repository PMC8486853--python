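# Methods

This note documents the models and procedures implemented in
`germcomp`, the parameters that matter, the design choices made where
the design was genuinely open, and what the synthetic-data generator
does and does not emulate.

## Coordinate and unit conventions

All intervals are 0-based, half-open (BED convention). Distances
between intervals, and between an interval and a point (a TSS), are
nearest-edge gaps: 0 when overlapping, otherwise the number of
intervening bases. Strand is ignored for distances; the TSS is the
strand-aware 5′ end of the gene model. Signal tracks are fixed-bin
per-chromosome vectors of mean per-base coverage; methylation levels
are reported on a 0–100 percent scale.

## Enhancer catalog

Peaks from all replicates are pooled and merged transitively whenever
two intervals overlap or their gap is **≤ 1000 bp** (inclusive at
exactly 1 kb; "within 1 kb" is read with the usual interval-merge
`-d`-style semantics). Promoters are TSS ± 2000 bp, clipped at
chromosome bounds, and are subtracted base-wise together with any
blacklist; intervals reduced to zero length are dropped.

Distal peaks are linked to genes through interaction anchor pairs: a
(peak, gene) link is emitted when one anchor lies within **1000 bp** of
the peak and the other within **3000 bp** of the gene's TSS, testing
both anchor orderings (the pair is unordered). One enhancer record per
peak aggregates all linked genes, so a catalog of 415 enhancers linked
to 216 distinct genes yields 1.9 enhancers per gene. Where interaction
data are absent, stage enhancer sets are assigned proximally: peaks
within **500 kb** of a gene-set TSS but farther than **3.5 kb** from
the TSS of *any* gene, assigned to the nearest gene-set gene
(ties break to the lexicographically smallest gene id). Whether the
anchor–peak distance in the original analysis was edge- or
midpoint-based is not documented; edge-based is used here.

## Chromatin signal

**RPGC normalization** divides every bin by one global factor so the
base-weighted genome-wide mean coverage equals 1 ("1× depth"). It is
idempotent and scale-invariant; an effective genome size may replace
the track's own span.

**Window quantification** reports the mean signal over
[midpoint − 1 kb, midpoint + 1 kb), clipped at chromosome bounds, with
partial bins weighted by overlap. "Within 1 kb of the enhancer" is
ambiguous between midpoint-anchored and edge-extended windows;
midpoint-anchored is the default and the anchor is exposed as an
option.

**Group classification**: per replicate, the EpiLC/EpiSC ratio of
window means with a pseudocount ε = 0.01 RPGC in numerator and
denominator (prevents division by zero in empty windows and is
negligible against typical signal ≈ 1). An enhancer is **Group I** iff
the ratio exceeds **1.2** (strict) in at least **2 of 3** replicates,
otherwise **Group II**. Raising the threshold can only move enhancers
from Group I to Group II (monotonicity).

**Paired effect size**: the Wilcoxon signed-rank statistic is computed
with zero differences dropped, midranks for tied |differences|, the
exact-null variance Σrᵢ²/4 (which equals the tie-corrected normal
approximation), and no continuity correction. The effect size is
r = z/√n with n the number of nonzero-difference pairs; |r| ≤ 1 always
(Cauchy–Schwarz), and a uniform shift (all |differences| tied) attains
r = 1. The 95% CI is a percentile bootstrap over resampled pairs
(1000 resamples, seeded); the interval is widened to contain the point
estimate if a small resample excludes it. The all-zero-difference case
degenerates to r = 0 with CI [0, 0] and a warning instead of an
exception, so pipelines survive constant inputs.

**Flank correlation**: per enhancer, both signals are averaged over one
500 bp bin immediately upstream and one immediately downstream of the
interval, the two bin means are averaged per enhancer ("two 500 bp bins
up- and downstream" is read as one bin per side), and Spearman's ρ is
computed across enhancers.

## scRNA-seq

Counts are normalized per cell to 10 000 total (counts-per-10k). The
differential test behind gene-set definition is a two-sided Wilcoxon
rank-sum on normalized expression with Benjamini–Hochberg adjustment;
the test is pluggable. The original analysis used a negative-binomial
likelihood test from an external toolkit; the rank test is
assumption-light and exactly reproducible, and correctness here is
judged on planted-marker recovery, not on matching another toolkit's
p-values. Membership requires, all strict: adjusted p < 0.005,
pct.1 > 0.2, pct.2 < 0.4 (expression fractions use raw count > 0) and
a positive log fold change.

Transcriptional noise selects the stage's 500 most variable genes by
dispersion (variance/mean of normalized counts; the selection criterion
behind "most variable" is not documented upstream, dispersion is this
package's choice), computes all pairwise Spearman correlations with
average ranks for ties, and transforms them to d = √((1 − ρ)/2) ∈
[0, 1]. Pairs involving a constant expression vector have undefined ρ
and are excluded with a warning rather than set to 0.

Gating uses (Dppa3 > 0.1 OR Prdm1 > 1) AND Klf4 < 1. The OR/AND
precedence follows the population label "Prdm1 or Dppa3⁺ / Klf4⁻": the
naïve marker vetoes unconditionally. The expression scale of the
original thresholds is implicit; normalized (counts-per-10k) expression
is the default and the thresholds are configuration-exposed.

Embryoid-body subpopulations are clustered by k-means on a supplied
low-dimensional embedding (k = 3 for day-2 and k = 4 for day-4 bodies
in the study; the embedding itself is an input, not computed here),
with 10 restarts and a fixed seed. Clusters are annotated against
candidate tissue marker sets (pre-filtered to log2 fold change > 2.5 by
the caller) with a one-sided hypergeometric enrichment of each set
among the cluster's upregulated genes (rank test, BH-adjusted p < 0.05,
positive fold change); the most significant tissue below a BH-adjusted
0.05 floor wins, otherwise the cluster is "undefined".

## Single-cell methylomes

CpG sites are kept at a read coverage of **3–100 inclusive**; cells are
kept when they cover **strictly more than 100** distinct CpG sites
within the region set ("CpG coverage > 10²" is interpreted as a site
count, consistent with the ≈150 shared CpGs per cell pair at these
loci; read depth is the plausible alternative). Pairwise dissimilarity
is the mean |Δ methylation rate| over CpGs covered in both cells and
inside the regions, ×100. On binary single-cell calls this equals the
fraction of discordant shared sites — the 0-or-1 scoring scheme — and
it generalizes to fractional rates. Pairs with no shared site are
undefined (flagged, never 0); pairs with fewer than 5 shared sites are
flagged low-confidence but reported (no floor is documented upstream;
5 is configurable). Stage heterogeneity is the mean over defined
within-stage pairs.

## Synthetic data

The generator produces every input at a toy scale chosen to keep the
full pipeline under ~5 s on one CPU: two 1 Mb chromosomes with 100 bp
bins, 50 genes, and 40 + 40 + 20 enhancers (class I / class II /
decoy), placed disjointly, > 3.5 kb from every TSS (so the
promoter-proximity rules are exercised non-trivially) and ≥ 3 kb apart
(so ± 1 kb windows never overlap a neighbor).

*Tracks.* Three replicates per stage. Each enhancer gets a lognormal
intensity factor (log-sd 0.5, shared across stages and replicates);
class I enhancers are additionally elevated by the configured fold
(default 2.0) in EpiLC only, applied across midpoint ± 1 kb so that the
windowed ratio equals the fold *exactly* in the zero-noise limit.
Replicate noise is multiplicative lognormal per bin (sd 0.1), which
keeps coverage positive and makes the windowed-ratio tail analytically
tractable: the window average over ~20 bins has log-sd ≈ 0.1/√20, so a
class-I ratio near 2 falls below 1.2 with probability ≪ 10⁻⁴ and label
recovery at ≥ 95% precision/recall is expected by construction, not by
tuning. The methylation track is hypomethylated inside planted H3K4me1
domains in proportion to the realized intensity, planting the negative
flank correlation.

*Interactions.* One true pair per class I/II enhancer (anchor ≤ 1 kb
from the enhancer, partner ≤ 3 kb from the target TSS) plus 40 decoys
whose first anchor is > 2 kb from every enhancer *and* > 4 kb from
every TSS, so the pair violates a distance rule under either anchor
ordering and linking must reject 100% of them.

*UMI matrices.* Negative-binomial counts (var = μ + φμ²) for three
pluripotent stages of 100 cells that differ only in dispersion
(0.6 / 0.1 / 0.6 for ESC / EpiLC / EpiSC) — making EpiLC the
lowest-noise stage by construction — plus a 200-cell embryoid body with
truth clusters (23 PGC-like, three extraembryonic-like). Marker genes
are nearly silent outside their own population (baseline mean 0.2–0.35
UMI), as real lineage markers are; this is also the only regime in
which the pct.2 < 0.4 filter is satisfiable. The PGC-like cluster
raises its 20 markers by the configured 4-fold and expresses
Dppa3/Prdm1 but not Klf4; ESC express Klf4. At the 4-fold effect and
φ = 0.4, per-marker detection power at n = 100 + 100 is ≈ 95%, so
whole-panel recovery is expected but an occasional single miss at an
arbitrary seed is sampling, not failure. A well-separated 2-D blob
embedding accompanies the embryoid-body cells.

*Methylomes.* Per stage, cell and enhancer, a methylation level is
drawn from Beta(c/2, c/2); the concentration c sets the cross-cell
variance 0.25/(c + 1). Defaults c = 8 / 2 / 50 for E4.5 / E5.5 / E6.5
plant the ordering E5.5 > E4.5 > E6.5; the uniform level at c = 2 gives
an expected pairwise dissimilarity of 1/3, matching the ~30% scale
observed for the most heterogeneous stage in vivo. Ten CpGs per
enhancer (positions fixed per genome), Bernoulli site dropout
(coverage probability 0.6), read depth 1 + Poisson(12), methylated
reads binomial given the level.

All generators draw from independent substreams of one master seed
(seed plus a fixed stream offset), so adding a replicate or stage does
not perturb the others, and every output is byte-reproducible.

**What the generator does not emulate:** read-level artifacts, GC and
mappability bias, realistic peak shapes or contact matrices,
doublets/ambient RNA, bisulfite conversion errors, and correlated
noise between replicates. Passing the recovery suites therefore shows
that the *operations* implement their stated rules and recover planted
signal at realistic effect sizes and noise — not that the thresholds
are optimal for any particular real dataset.

## Numerical notes and limitations

- BH adjustment is applied per invocation (per gene-set call, per
  cluster, per annotation), mirroring per-comparison correction.
- k-means determinism relies on a fixed seed and 10 restarts; distinct
  seeds may permute label ids (annotation is label-id agnostic).
- The pairwise dissimilarity is O(cells² × sites); at the study scale
  (hundreds of cells, ~150 shared CpGs) this is milliseconds.
- The bootstrap CI is percentile-based; for |r| near 1 the interval is
  extremely narrow and is clamped to contain the point estimate.
- `run_pipeline` orchestrates the synthetic demonstration end to end;
  external datasets are analyzed through the per-stage subcommands,
  which accept the documented plain-text formats.
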