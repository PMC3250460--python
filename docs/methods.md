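# Methods

This note documents the statistical procedures implemented in `methex`,
the assumptions behind them, the synthetic-data model used to exercise
them, and the numerical/design choices made where a convention had to be
fixed.

## Scope and data model

The package analyses promoter methylation and gene expression changes
between tumour and normal samples across independent datasets. Inputs
are probe × sample Beta-value matrices (or raw methylated/unmethylated
signal pairs, HumanMethylation27-style), gene × sample log2 expression
matrices, sample sheets (group, batch, laboratory, patient), probe→gene
annotation tables and GMT gene-set collections. Array normalisation
(RMA/LVS), IDAT parsing and probe QC are out of scope: the package
consumes already-normalised matrices.

Beta values are computed as `β = M / (U + M + 100)`; the +100 offset is
Illumina's stabilising constant and bounds β in [0, 1). β is monotone
increasing in M and decreasing in U.

### Probe→gene collapsing

Tests run per probe; probe-level results are collapsed to genes by the
**minimum-p representative**: per gene, the probe with the smallest p,
ties broken by larger |Δβ| and then lexicographically smaller probe id,
so the mapping is deterministic. Genes whose mapped probes disagree in
direction carry a `discordant_probes` flag. This is a convention, not a
uniquely correct choice; on HM27-like designs most genes have a single
promoter probe, making the convention moot in the common case. Whether
published analyses of this kind tested probes or pre-collapsed genes is
generally not reported.

## Batch-effect diagnosis

Batch susceptibility per probe is a one-way ANOVA of Beta on the
categorical batch (or laboratory) label — a single F and p per probe,
BH-adjusted across tested probes; the susceptible fraction is the share
of tested probes with q below the threshold (default FDR < 0.05). With
two groups the F statistic equals the square of the pooled-variance
two-sample t statistic; the test suite checks this identity numerically.
Probes with zero total variance are skipped and counted; zero
within-group variance with distinct group means is reported as F = ∞,
p = 0.

Sample-level structure is assessed by average-linkage hierarchical
clustering on Euclidean distances between Beta profiles, cut into as
many clusters as there are batches; the report states whether the cut
reproduces the batch partition exactly and gives the adjusted Rand
index (0 expected under no batch structure, 1 for a perfect split).
The linkage method is configurable; average linkage is the default.

The corruption demonstration calls differential methylation for two
tumour batches against one shared normal group (unpaired) and scores
the direction consistency of the shared DM calls. With opposing batch
offsets and no true signal, both comparisons produce large DM lists
whose directions disagree almost completely — differential methylation
driven by batch, not biology.

## Differential calling

**Methylation** uses a per-feature two-sided t test — Welch by default;
paired-by-patient when the design is pair-matched (the recommended mode
for cohorts where each patient contributes one tumour and one normal
sample) — with Benjamini–Hochberg control across all tested features.
Direction is *hyper* when Δβ = mean(tumour) − mean(normal) > 0, *hypo*
when negative; Δβ = 0 exactly leaves the direction undefined ("none")
and such features are excluded from direction-based summaries. Features
that are constant in both groups get p = 1; constant groups with
different means get p → 0.

**Expression** uses the SAM statistic `d = (mean_T − mean_N)/(s + s0)`
with pooled standard error `s` and fudge constant `s0`. `s0` is chosen
by minimising the coefficient of variation of the spread (normalised
MAD) of `d` across deciles of `s`, evaluated over the 0, 5, …, 100
percentiles of `s`; the median of `s` is the fallback and can be forced
with `s0="median"`. Group labels are permuted — exhaustively when the
number of distinct assignments does not exceed the requested count,
otherwise by seeded sampling — to form expected order statistics and
the FDR estimate. For a symmetric threshold Δ on the deviations between
observed and expected order statistics, the cut points define the
called set; the number of false calls is estimated from the
per-permutation counts of permuted d beyond the cuts, and the smallest
Δ whose estimated FDR is at or below the requested level defines
significance. Per-gene q values are the estimated FDR at a symmetric
cut at each gene's own |d|, monotonised so q never increases with |d|.

Two numerical choices deserve note:

* **False-call estimator.** The classic choice is the *median*
  per-permutation count. At extreme cuts this estimator collapses to
  zero (more than half of the permutations have no value beyond the
  cut) while the observed data calls a gene, producing an estimated FDR
  of exactly 0 and, on global-null simulations, empirical FDR an order
  of magnitude above nominal. The default here is therefore the *mean*
  count, which is calibrated in the same simulations; `median` and the
  conservative 90th percentile (`p90`) remain available via
  `SAM(fdr_estimator=...)`.
* **Residual optimism.** Even with the mean estimator, scanning many
  candidate Δ values and keeping the first that clears the target is a
  selection over thresholds; on 200-gene global nulls the empirical
  probability of any call at nominal FDR 0.01 is ≈0.03–0.04. This is a
  property of the SAM thresholding scheme itself and is within the
  Monte-Carlo error of the 50-replicate calibration checks, but SAM's
  q values should not be read as exact.

The DE FDR default is 0.01 (the stricter of the two conventional
levels, used for headline DE analyses); DM and batch FDR default to
0.05. Effect filters are inclusive: |Δβ| ≥ t keeps a gene at exactly t,
and a linear fold-change threshold f keeps |log2FC| ≥ log2(f).

## Reproducibility scoring

For two significant-gene lists of lengths L₁ and L₂ sharing k genes,
POG₁₂ = k/L₁ and POG₂₁ = k/L₂. Counts are stored as exact integers and
percentages derived at formatting time, so `pog12·L1 = k` holds exactly.
Direction consistency of the shared genes is tested against an exact
one-sided binomial null with agreement probability ½ (two directions
equally likely by chance); the tail is computed by log-space summation
of binomial log-pmfs, because the double-precision survival function
underflows around 10⁻³⁰⁸ while all-consistent overlaps of a few
thousand genes have tails near 10⁻¹⁰⁰⁰ — both the probability and its
log10 are reported.

Shared-gene consistency compares the two lists' *assigned directions*;
solely-detected genes (significant in one dataset only) are instead
checked against the *sign of the effect* in the other dataset's full,
unthresholded results — a deliberate distinction, since the second
dataset assigns no direction label to non-significant genes. Genes
missing from the other dataset, or with an exactly zero effect there,
are excluded and counted.

Proportions of hypermethylated genes between two gene groups are
compared with Pearson's chi-squared test on the 2×2 table, without
continuity correction (configurable counts only; a zero margin is an
error).

## Methylation–expression concordance

For genes measured on both platforms, the hyper-side concordance rate
is the fraction of down-regulated genes among hypermethylated genes
that are differentially expressed; symmetrically hypo/up. Significance
is an upper-tail hypergeometric test: draws are the hypermethylated-DE
genes, successes the DE-down genes, the population the **universe of
genes tested on both platforms** (post-collapse, pre-significance).
The universe choice is consequential and not uniquely determined by
common practice; it is surfaced in every report. When two datasets per
platform are supplied, significance is restricted to genes reproducibly
significant with consistent direction (effects taken from the first
dataset). A threshold sweep applies the Δβ and fold-change filters over
a grid (defaults {0, 0.15, 0.3} × {1, 2}) and emits one report per grid
point, without any inference about monotonicity.

## Gene-set enrichment

Plain hypergeometric over-representation of a query list against GMT
sets within an explicit universe, BH-adjusted across sets. Sets are
intersected with the universe first; query genes outside the universe
are dropped and logged. Topology-aware GO algorithms (e.g. Elim-style
decorrelation of the GO graph) are intentionally not implemented — the
package is download-free and carries no GO DAG — so term lists will
differ from analyses that used them. The universe defaults to all genes
tested for differential methylation in the run.

## Synthetic cohorts

The generator emulates the structure of the real studies without
modelling chip physics:

* **Baselines.** Per-probe baseline β is drawn from a two-mode
  distribution (logit-normal around 0.1 and 0.8, sd 0.5 on the logit
  scale, equal weights) mimicking CpG-island bimodality.
* **Effects on the logit scale.** Differential shifts, per-batch
  offsets (N(0, batch_sd²), shared by every sample in the batch) and
  within-group noise (N(0, noise_sd²)) are added to logit(β) and mapped
  back, keeping β inside (0, 1). The differential shift is calibrated
  per probe so the noise-free tumour−normal difference equals
  ±delta_beta_effect exactly (clipped near the boundaries).
* **Design.** Each patient contributes one tumour and one normal sample
  in the same batch. `generate_two_batch_replicates` draws two
  independent cohorts (independent offsets and noise) from one shared
  truth, emulating a study's two largest batches treated as independent
  datasets.
* **Truth counts.** Exactly `round(frac_dm · n_probes)` probes are
  truly DM, assigned gene-blockwise so a gene's probes share one
  direction; `round(frac_hyper_among_dm · n_DM_genes)` of the DM genes
  are hypermethylated.
* **Coupling.** Every truly DM gene is truly DE: down with probability
  `concordance_hyper` (up otherwise) if hypermethylated, up with
  probability `concordance_hypo` (down otherwise) if hypomethylated.
  A background fraction of non-DM genes is DE in a random direction.
  Expression is log2-scale: gene baselines N(8, 2²), a fixed ±lfc_effect
  shift for DE genes in tumours, N(0, 0.5²) within-group noise.
* **Signals.** `signals_from_beta` emits (M, U) pairs with a fixed
  total intensity consistent with a target β, to exercise the
  Beta-computation path end to end.

Default parameter values describe a well-powered paired design: two
batches of 30 tumour/normal pairs, 2000 genes with one probe each
(probes_per_gene > 1 supported), frac_dm = 0.1, |Δβ| = 0.3,
batch_sd = 0.2, noise_sd = 0.3, concordance_hyper = 0.9,
concordance_hypo = 0.6, background DE 0.1, |log2FC| = 1.5. The
calibration and recovery checks in the test suite use cohorts of
100–2000 probes and 10–30 pairs per batch, 20–50 replicates where a
distribution over seeds is needed; these sizes are the package's
chosen simulation conditions and are stated in the tests themselves.
No published study reports generative effect-size distributions for
such data; the values above are conventions and flagged as such.

**What the generator does not model** — probe cross-hybridisation,
SNP-affected probes, copy number, spatially correlated chip noise,
non-Gaussian heavy-tailed expression noise, or batch effects in the
expression cohorts. Passing recovery tests on these cohorts therefore
demonstrates correctness of the statistical machinery under a clean
generative model, not robustness to every artefact of real arrays.

## Determinism

All randomness flows from explicit seeds: the generator derives
independent streams from `(seed, stream-id)` seed sequences, SAM
permutations from `random_state`, and the pipeline threads one
top-level seed through every stage, so identical configuration and seed
reproduce outputs byte for byte.

## Known limitations

* SAM significance is threshold-scan based and slightly optimistic at
  very small nominal FDR (see above); its band-based `significant` flag
  and the per-gene q values can disagree near the boundary.
* The hypergeometric concordance p values depend on the documented
  universe choice and are not comparable to analyses with a different
  (unstated) background.
* Per-probe ANOVA treats batches as exchangeable groups; it does not
  model nested laboratory/batch structure.
* Missing values are handled by dropping the affected features per
  analysis (logged), not by imputation.
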