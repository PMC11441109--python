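# Methods

`xksilence` infers miRNA-mediated gene silencing — endogenous and
cross-kingdom — from a dual-species small-RNA / mRNA sequencing design in
which a plant and a fungus are profiled alone and in interaction.  This
note describes the statistical model behind each stage, the synthetic
experiment generator the test suite runs against, and the numerical
choices made where the design was genuinely open.

## Read triage

Small-RNA reads are kept when 18–32 nt long (boundaries inclusive),
cleaned of structural-RNA fragments (rRNA/tRNA/sn(o)RNA), collapsed to
unique sequences per sample, and assigned to a species by approximate
substring search against the two transcriptomes: a read "maps" to a
species when the read or its reverse complement occurs inside any
transcript of that species within `max_errors` edits (default 1 for
species assignment, 0 for structural removal; substitutions, insertions
and deletions all count).  Reads matching both transcriptomes are
*ambiguous* and excluded downstream; reads matching neither are
*unmapped*.  The four classes partition the input exactly, weighted by
read multiplicity.

Matching is deliberately transcriptome-based and splice-free: at the
scale this package targets there is no intron structure to resolve, and
the silencing-oriented quantities (antisense counts per transcript)
live naturally on transcripts.  A read hitting several transcripts of
one species is counted once per transcript, capped at 200 placements,
each weighted `1/n_placements`, so totals are conserved.  Match
coordinates are 0-based, half-open; "antisense" means the read matches
the reverse complement of the transcript, the orientation relevant for
silencing.  Approximate matching is delegated to `edlib` (infix
alignment); the test suite verifies exact agreement with an independent
neighborhood-enumeration oracle.

## miRNA quantification

Each mature catalog sequence is counted in the cleaned, collapsed reads
of every sample: a read contributes its multiplicity when the mature
sequence occurs *within* the read at edit distance ≤ 1.  Indels are
allowed by default (the error model of `agrep`-style tools); a
substitution-only Hamming mode is exposed as a switch because "one
mismatch" is also commonly read that way.  Counting is strand-specific,
and a read may count toward several near-identical catalog entries
(isomiR families) — the behaviour of independent per-miRNA searches.
A miRNA is *detected* when its summed counts reach 50 copies
(inclusive).

## Differential expression

Transcript counts are normalized with median-of-ratios size factors
(median over features with all-positive counts of count/geometric-mean).
miRNA count tables are instead normalized by sequencing depth (total
clean reads): a miRNA table holds a handful of features that are often
co-regulated, so within-table totals would absorb genuine global shifts;
depth factors side-step that composition artifact.

The two-group test is a negative-binomial Wald test:

* group means of normalized counts, with a 0.5 pseudocount;
  `log2FC = log2((mean_b + 0.5) / (mean_a + 0.5))`;
* a per-feature method-of-moments dispersion pooled across groups,
  `d = (pooled_var − pooled_mean) / pooled_mean²`, **moderated** toward
  the across-feature median with a prior weight of 10 df — the simplest
  form of the information sharing DESeq2 and edgeR perform.  At three
  replicates per group the raw 4-df moment estimate is far too noisy:
  un-moderated, the test's type-I error is calibrated but its power for
  a 16-fold shift collapses to ~0.66, because a chance over-estimate of
  the dispersion inflates the standard error of exactly the feature
  that matters.  With moderation, type-I error stays at 0.048–0.056 at
  nominal 0.05 and power is 1.0 (both measured by the acceptance
  checks);
* a delta-method standard error of log2FC,
  `Var(mean) = (μ + dμ²)/n`, and a Wald statistic referred to a
  t distribution with `n_a + n_b − 2 + 10` df, matching the plug-in
  variance's effective degrees of freedom;
* Benjamini–Hochberg adjustment across all features of one contrast;
* calls: `up`/`down` need `|log2FC| ≥ 1.5` **and** `FDR < 0.05`;
  features with all-zero counts are dropped before testing.

This is not a DESeq2 reimplementation — no shrinkage of fold changes,
no trended dispersion, no independent filtering.  Downstream stages
consume only sign/threshold calls, which is what the calibration and
recovery checks target.

Term enrichment is a one-sided hypergeometric upper-tail test per flat
term label, BH-corrected, `enriched ⇔ FDR < 0.05`.

## Target inference

Every candidate (miRNA, transcript) pair passes through four filters in
fixed order; the verdict records the first failure.

1. **Consensus.**  ≥ 2 plant-style tool votes or ≥ 3 animal-style tool
   votes.  External prediction tables (TSV: mirna, transcript, tool,
   style, score) are consumed as votes; two built-in plant-style
   predictors make the stage self-contained:
   * an *expectation* scorer: slide the reverse-complemented mature
     sequence along the transcript without gaps; per miRNA position
     (1 = 5′) Watson–Crick pairs cost 0, G:U wobble 0.5, mismatch 1.0,
     doubled within the seed (positions 2–13); the best site is reported
     when its score is ≤ 5.0.  This is a convention-driven surrogate,
     not a reimplementation of any published plant target predictor;
   * a *seedmatch* predictor: perfect Watson–Crick complementarity of
     positions 2–13 anywhere on the transcript.
2. **Opposite expression.**  The miRNA must be differentially expressed
   (thresholded call), the transcript significantly changed (FDR only,
   no fold-change threshold — a repressed target need not move 2.8-fold),
   and the two signs must be opposite.
3. **Anticorrelation.**  Spearman correlation (mean ranks on ties) of
   size-factor-normalized counts across matched samples must be
   ≤ `spearman_max`.  Two profiles: lenient (−0.4, the default) and
   strict (−0.7).  Pearson is computed and reported but takes no part in
   the verdict.  Pairs with a constant vector are rejected as
   degenerate; fewer than 4 shared samples also rejects.
4. **Background.**  The pair's correlation must be lower than the same
   miRNA's correlations with every other transcript of the target's
   organism: with a single target-side value the one-sided rank test
   degenerates to the empirical percentile
   `p = (1 + #{background ≤ r}) / (1 + n_background)`, passed strictly at
   `p < 0.1`.  Backgrounds under 10 values are flagged low-powered — at
   n = 9 the smallest attainable p is exactly 0.1, which never passes.

**Correlation sample set.**  Correlations use the samples of every
condition in which *both* features' species are physically present: an
endogenous pair uses its species' mono-culture control plus all
interaction conditions; a cross-kingdom pair uses the interaction
conditions only.  Including samples where one organism is absent would
fill the vectors with structural zeros: every transcript of the missing
species would then anticorrelate with any miRNA of the present one, a
confound that drowns both the pair correlation and the background
distribution.  Restricting to co-presence removes the artifact at the
cost of fewer samples per correlation.

Cross-kingdom vs endogenous classification follows the species labels;
retained pairs sort by Spearman correlation ascending, and the output
table is byte-deterministic for identical inputs.

## Synthetic experiment generator

The generator produces a complete two-species experiment — references,
miRNA catalog, count matrices, per-sample read pools, and a ground-truth
manifest — from one RNG stream keyed by the seed, consumed in fixed
stage order, so outputs are byte-identical across runs.

**Design.**  Five conditions, three replicates each: plant control,
fungus control, wildtype interaction, and two RNA-silencing-mutant
interactions.  miRNAs that participate in a planted pair are
*responsive*: knocked down `2^-3` in the wildtype interaction, fully
restored in the first mutant interaction and half-restored in the second
(a Dicer-deletion series; the three distinct levels across interaction
conditions are what make the planted anticorrelation identifiable for
cross-kingdom pairs, whose correlations see interaction samples only).
Replicate-level miRNA abundance wobbles by a log-normal factor with
0.5 log2 units of spread, which propagates into the targets and carries
the within-condition component of the anticorrelation.

**References.**  Uniform-random transcripts (300–1500 nt); a configurable
fraction of fungal transcripts is duplicated verbatim into the plant set
to create genuinely ambiguous reads; three random 120-nt structural
references model the rRNA/tRNA contaminant space.

**Planted pairs.**  Each pair embeds the exact reverse complement of the
mature sequence into its target transcript at a recorded position.
Cross-kingdom pairs link plant miRNAs to fungal transcripts; endogenous
pairs stay within species.  The target's mean in sample *j* is

    μ_tj = base_t · 2^(rep·[j is interaction]) · 2^(−rep · a_mj / base_m)

with `rep = repression_log2fc` (default 3.0), `a_mj` the miRNA's
realized abundance and `base_m` its control-level expectation; the
second factor applies wherever the miRNA's species is present.  The
baseline is thereby the *fully repressed* state: lowering the miRNA
derepresses the target, producing the opposite-sign differential
expression and the across-sample anticorrelation the inference looks
for, and `rep = 0` makes planted targets distributionally identical to
background — the null configuration used for specificity checks.

**Counts.**  Negative-binomial draws (`Var = μ + dμ²`, dispersion 0.05
by default, Poisson in the small-dispersion limit), zero where the
species is absent.  Ten planted DE transcripts per species shift their
mean `2^±U(2,6)` in all interaction samples.

**Reads.**  Each sample's pool of exactly `reads_per_sample` reads is a
multinomial over: structural windows (10%), mature-miRNA copies
proportional to the abundances (≈25% at control level; at most one
substitution per copy, applied with probability `1−(1−e)^L`), and
transcript degradation fragments (uniform position, both strands,
lengths 16–34 nt, hence partly outside the retention range) filling the
remainder.  Qualities are constant; trimming is upstream of this
artifact and not modelled.

**What the generator does not emulate:** hairpin/precursor structure,
adapter contamination, ligation and PCR bias, positional degradation
bias, isomiR ladders, genome-level repeats beyond the planted
homologous transcripts, and library-size variation between samples.
Passing the recovery checks therefore demonstrates that the inference
chain is correct and calibrated under its own model assumptions — not
that those assumptions hold for any particular real library.

## Descriptive summaries

Length and 5′-base distributions are multiplicity-weighted fractions
(invariant under collapsing).  The percentile-rank panel ranks genes by
antisense sRNA count (zero-count genes excluded; mean ranks on ties,
scaled to (0,100]), bins into right-closed quintiles, and compares mean
normalized expression between bins by one-way ANOVA with Tukey HSD;
compact letters come from insert-and-absorb (groups sharing a letter are
not significantly different).  qPCR quantities: relative expression by
2^−ΔΔCt (replicate Ct values averaged per condition) and root
colonization as the fungal/plant marker-DNA ratio, accepting either
2^−Ct-derived or standard-curve quantities.

## Problem sizes

The shipped defaults — 100 transcripts per species, 10 miRNAs, 5
cross-kingdom + 4 endogenous planted pairs, 15 samples, 2 000 reads per
sample — were chosen so that a complete simulate-and-recover cycle runs
in about a second and the full test suite in well under a minute, while
every stage still sees non-trivial data (ambiguous reads, sequencing
errors, contaminants, planted and background DE).  Calibration studies
use 2 000 null features for the type-I check, 200 replicates for power,
20 seeds for null specificity, and 100 seeds for the anticorrelation
coupling oracle.

## Known limitations

* The background comparison with a single target-side correlation is an
  empirical percentile, not a true rank-sum test; with ~100 background
  transcripts its resolution is 0.01.
* With few samples the Spearman null is coarse (at n = 6 the value next
  to −1 is already −0.94), so strict profiles demand either strong
  coupling or more samples.
* The expectation surrogate is gapless; bulged or gapped sites must come
  from external prediction tables.
* DESeq2-style fold-change shrinkage is intentionally absent; log2FC
  estimates for low counts are noisy and should be read through the
  call column, not as point estimates.
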