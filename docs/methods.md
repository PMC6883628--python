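# Methods

This note documents the models and procedures implemented in
`brainaging`, the assumptions behind them, the defaults and why they were
chosen, and what the synthetic validation does and does not establish.

## The synthetic-data model

The generator (`brainaging.synthdata`) is the package's source of inputs
and its instrument of validation.  A study design lays out
`individuals × regions × hemispheres` libraries (defaults: 4 young + 3
aged individuals, 44 regions in two classes, both hemispheres — ~616
libraries, reducible by explicit dropout triples; test-scale runs use 8
regions).  Counts are drawn gene-by-gene from a gamma-Poisson
(negative-binomial) model, `Var = μ + αμ²`, with gene-wise dispersion α
log-normal (median 0.08, log-sd 0.5) and log-normal library sizes
(CV 0.3, default mean 2×10⁵ reads at 1,000–2,000 genes).  The log₂ mean
stacks:

* a gene baseline (sd 1.5 log₂ units);
* ± log₂ FC for planted DEGs in aged samples (linear FC, default 1.5–2);
* one latent factor per planted module: gene i in module m gets
  `σ·(√r·f_m + √(1−r)·ε_i)` with σ = 1 log₂ unit and the target
  intra-module correlation `r` set per age group — unequal r plants a
  connectivity gain or loss without changing any marginal variance.
  Hub genes are coupled to `f_m` at 0.995; aged-specific drivers at
  0.995 in aged samples only and independently otherwise;
* batch, sex, and latent sample-quality effects (per-gene normal betas);
* a per-sample quadratic GC-content bias and the library-size offset.

Exon counts partition each gene's count by a per-group multinomial usage
vector; only DEU genes change usage between groups (default: the first
exon moves from 0.30 to 0.50 of the gene's reads).

Two deliberate departures from a naive construction:

* **Fixed-denominator scaling.**  Per-sample renormalization of relative
  abundances would leak every planted factor into every gene's mean
  through the library total (compositional coupling) and attenuate
  planted correlations; the generator instead scales by the dataset-wide
  mean total.  Compositionality still enters — realistically — at the
  *analysis* stage through CPM normalization, which is why planted
  modules are kept to a modest share of the library (module genes get a
  +0.5 log₂ expression bump, not more).
* **Noise-compensated coupling.**  Measurement noise adds roughly
  `(α + 1/μ)/ln²2` of log₂ variance on top of the latent signal, so the
  latent correlation is inflated by the corresponding variance ratio so
  that the *realized* log-expression correlation lands on the requested
  target.  Realized intra-module correlation at 40 samples is within
  ~0.05–0.08 of target (the residual gap is CPM coupling plus the
  sampling distribution of mean pairwise correlation).

What the generator does **not** emulate: read-level artifacts
(alignment, duplication), isoform structure beyond exon usage vectors,
individual-level random effects (samples are conditionally independent
given the design), region-specific co-expression topology, and any
realistic gene-gene causal structure.  Passing the recovery suites
therefore shows that each stage detects the statistical signatures it
targets at realistic effect sizes and sample counts — not that it would
be similarly powered against the full messiness of real tissue data.

## Quality control

RIN ≤ 5 excludes a sample (boundary inclusive, i.e. 5.0 fails).
Quality z-scores use the sample standard deviation (ddof = 1) over the
samples under evaluation; by default they are computed after the RIN
filter (configurable, since the ordering is a free choice); a constant
metric yields z = 0 so it can never create outliers.  The signed
direction table is authoritative: %Intergenic Bases, GC Dropout and AT
Dropout are outliers high (z > 2); %Total Reads, %High-quality Aligned
Reads, %mRNA Bases and Median 5′→3′ Bias are outliers low (z < −2).  A
sample with more than one outlier metric is removed.  Gene filtering is
per stratum (cortex / non-cortex) at ≥ 10 counts in ≥ 80% of samples,
both boundaries inclusive; a gene detected in either stratum counts as
detected, and per-stratum sets are kept for stratum-specific analyses.

## Normalization and covariate removal

Expression is log₂(CPM + 1) (exactly invariant to depth rescaling).  GC
and length correction is a documented smooth-regression correction, not a
re-implementation of conditional-quantile normalization: each sample's
deviation from the per-gene mean is regressed on a cubic polynomial in
GC fraction plus log length and the fit subtracted, which removes
sample-specific GC/length trends while preserving per-gene means up to a
constant.  Sequencing surrogates seqSV1/seqSV2 are the first two PCs of
the centered (not scaled) quality-metric matrix — on the generator's
metric block they carry ~99% of the variance, matching the rationale for
using exactly two — with signs fixed by making each component's
largest-magnitude loading positive.  Covariate adjustment fits per-gene
OLS on an intercept plus the encoded covariates (batch, sex, seqSV1,
seqSV2 in the pipeline) and subtracts the covariate contribution only;
age group and region are never in this design, because they are the
biology under study.  Region indicators are regressed out by the same
machinery immediately before module construction, and only there.
Collinear designs are rejected by rank check rather than silently
pseudo-inverted.

## Connectivity

A region's profile is the per-gene mean over the group's samples in that
region (hemispheres pooled by default; configurable).  Connectivity
matrices are Pearson (or Spearman) correlations over all region pairs;
the young/aged comparison is a two-sided Mann-Whitney U with continuity
correction on the upper-triangle values (full rectangle for the
right × left hemisphere matrix).  An all-tied degenerate comparison
reports p = 1.  Region dendrograms use average linkage on 1 − r with
input order as the deterministic tie-break.

## Differential expression and exon usage

The DE engine is an in-repo NB Wald test, not a DESeq2 port: size
factors by median-of-ratios over all-positive genes; gene-wise dispersion
by pooled within-group moments of normalized counts, floored at 1e−8;
the group log-fold-change tested with a delta-method standard error and
referenced to a t distribution with n − 2 degrees of freedom.  The t
reference is the small-sample choice that keeps the null rejection rate
at 0.05 within [0.03, 0.07] at 10 vs 10 samples (the normal reference is
anticonservative there); with the study's sample counts the two
references agree closely.  Genes with an all-zero group are reported at
p = 1, log₂FC = 0, flagged `degenerate`.  DEG calling is strict:
p < 0.05 and linear |FC| > 1.5 (the conventional linear reading of the
1.5 cutoff; a config switch could reinterpret it on the log scale).
Set overlap is Jaccard (defined as 0 for two empty sets);
over-representation is one-sided Fisher.  Cell-type sets follow the
inclusive ≥ fivefold specificity rule over the five brain cell types; an
all-zero reference gene stays unassigned.

Exon usage is tested per exon on the group-pooled 2×2 table (exon vs
rest of gene), χ² with Yates correction, Fisher's exact when any
expected cell is below 5, BH across exons; a gene is a DEU gene when any
exon falls below p = 0.01 (the any-exon aggregation rule, configurable).
Pooling ignores between-sample overdispersion, which is acceptable under
the generator's multinomial usage model (null calibration at the 0.01
level verified) but optimistic for real data; `method="logit_t"` provides
an overdispersion-robust per-sample logit-usage Welch test.

## Modules and MDC

Module detection runs on aged-group expression: unsigned adjacency
|r|^β, TOM similarity, average-linkage clustering of 1 − TOM, static cut
at height 0.97, minimum size 24 (the smallest module the analysis is
expected to resolve), then iterative merging of modules whose eigengenes
(first PC of the standardized submatrix, sign-aligned with the mean
profile) correlate above 0.75.  The static cut replaces the dynamic
hybrid cut as a simpler, testable rule; 0.97 was calibrated on the
generator's planted-module fixtures and is exposed in config, as is
everything else.  Soft-threshold selection picks the smallest power
whose degree distribution reaches scale-free fit R² ≥ 0.8 with negative
slope *and* retains mean connectivity ≥ 1 (without the floor, large
powers that crush the network to near-zero degree can pass the fit
spuriously); the fallback, and the pipeline default, is the conventional
unsigned power 6.

MDC for a module is the ratio of mean pairwise |r|^β in aged samples to
the same quantity in young samples, computed at the detection power
(switchable to raw correlations).  Because a ratio cannot be negative,
gain and loss are judged on log₂ MDC: significance comes from a
group-label permutation null (default 1,000 permutations; two-sided
p with the +1 correction), BH across modules, gain iff log₂ MDC > 0 with
q < 0.05, loss iff < 0 with q < 0.05.  Module "importance" is the number
of regions whose DEG set is Fisher-enriched in the module at q < 0.05,
ties broken by mean −log₁₀ q; cell-type annotation reuses the Fisher
machinery per module.

## Key drivers

Mutual information uses equal-frequency binning with
B = max(2, ⌊√n/2⌋) bins and the Miller-Madow occupancy correction by
default (the raw plug-in MI of independent vectors is biased up by about
(B−1)²/2n, which at module sample sizes would swamp weak edges);
summation order is canonicalized so MI is exactly symmetric in its
arguments.  Edge significance uses a permutation null of MI between
independently shuffled vectors with the (1 − α/n_pairs) Bonferroni
quantile as threshold.  DPI pruning processes edges in ascending MI
order and removes an edge when a common neighbor makes it the weak leg
of a triangle below (1 − tolerance) of the smaller of the other two legs
(tolerance 0.15, the customary ARACNE value); the result matches a
brute-force fixpoint triangle scan.  Hubs are the top 5% of degree with
ties included (both the fraction and the N of NHNN are unspecified
conventions exposed in config; defaults 0.05 and N = 2); aged-specific
hubs are aged hubs minus young hubs over the same node universe; NHNN
counts distinct nodes within N hops by BFS, ranked descending with label
tie-breaks.

## Problem sizes and numerical choices

Validation fixtures use 8 regions, 500–2,000 genes, modules of 30–60
genes, 200–500 permutations and 20–50 replicates — sizes at which every
suite runs in seconds to a few minutes on one CPU while leaving the
detection problems non-trivial.  All randomness flows from explicit
seeds; module detection and DPI are deterministic and invariant to input
order; degenerate inputs (constant metrics, all-zero genes, single-exon
genes, all-tied comparisons, sd = 0, empty sets) take documented
non-crashing paths.

## Known limitations

The DE and DEU engines are defined, calibrated stand-ins with the same
decision contracts as DESeq2/DEXSeq, not re-implementations; results on
real data would differ in detail.  Samples are treated as exchangeable
within groups — there is no individual-level random effect, in the
generator or the tests.  Module preservation against external reference
cohorts and functional (GO/KEGG) enrichment are out of scope.  The
static tree cut trades the adaptivity of the dynamic hybrid cut for
auditability; on data with strongly nested module structure it will be
cruder than WGCNA's default.
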