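# Methods

`targetscreen` re-implements, as a reusable and testable pipeline, the
statistical core of an integrated target-validation screen: siRNA knockdowns
of candidate genes in two microglial cell backgrounds (a control line and a
sensitized Psen2-knockdown line), read out by cellular phenotype assays and
quantitative proteomics, and integrated into per-target verdicts.  This note
documents the models, the parameters that matter, the synthetic study the
package validates itself against, and the numerical choices that were
genuinely open.

## Phenotypic hit calling

Raw assay readouts (fluorescence / luminescence intensities) arrive as
replicates nested in experimental batches.  The analysis chain is:

1. **Batch averaging and log2FC.** Replicates are averaged per batch on the
   raw scale; the log2 fold change of each target siRNA against the control
   siRNA is computed within the same assay, cell line, batch and — for the
   NFkB reporter — LPS dose.  Because target and control share a batch, any
   multiplicative batch effect on the raw readout cancels here.
2. **Random-intercept mixed model.** Per assay (and dose), log2FC is modeled
   with fixed siRNA-by-cell-line cell means and a random intercept per batch,
   fitted by REML (statsmodels `MixedLM`).  Cell lines are never mixed in a
   contrast; each marginal mean is a per-(siRNA, cell line) effect.
3. **Marginal-mean tests, BH, hits.** Each cell mean is tested against zero
   with a Wald ratio referred to the normal distribution (a `wald_reference:
   t` switch uses a t with residual degrees of freedom instead; at the
   screen's batch counts the difference is negligible, and the normal
   reference is deterministic and simple).  p-values are BH-adjusted within
   each (assay, cell line, dose) family — the narrowest defensible family;
   `phenotype_bh_family: assay` pools a whole assay instead.  A hit is any
   adjusted p ≤ 0.05, boundary inclusive.

Degenerate designs are downgraded rather than refused: with fewer than two
batches, or at most one observation per batch (where batch and residual
variance are inseparable), or when REML lands on the zero-variance boundary,
the fit becomes ordinary least squares — to which the mixed model reduces
exactly at zero batch variance.  The REML optimizer retries bfgs → powell →
cg → nm; a rare line-search failure in one optimizer does not silently
change the model.

## Proteomic differential abundance

Samples with fewer than a configured number of quantified proteins
(default 6,100, the screen's cutoff; strict "fewer than", so a sample at
the threshold is retained) are excluded before testing.  Within each cell
line, each protein is tested across all siRNA groups by one-way ANOVA, with
Tukey's HSD (Tukey–Kramer under unequal group sizes) adjusting every
target-vs-control pairwise contrast.  Missing intensities are handled
complete-case per protein per group; groups under `min_obs_per_group`
(default 3) drop out of that protein's test.  Zero residual variance with
unequal means is emitted as a flagged infinite-F record (p = 0) rather than
an error; all-identical values give F = 0, p = 1.

The studentized-range tail probability is computed by a vectorized
Gauss–Legendre double quadrature over the scale-mixture representation
(80-node inner integral over the normal range statistic, 64-node outer
integral over the chi distribution of the pooled SD).  Agreement with an
independent implementation is part of the test suite at 1e-6; the measured
worst error is ~4e-8.  The motivation is throughput: per-protein Tukey
contrasts over a proteome require tens of thousands of tail evaluations.

The per-contrast log2FC (difference of group means on the log2 scale) is
the ranking statistic passed to enrichment, and each knockdown's own
protein is reported separately (`target_self_effects`) as a built-in
positive control: a working knockdown should show a negative own-gene
log2FC.

## Preranked gene-set enrichment

The engine is the weighted Kolmogorov–Smirnov running-sum statistic.
Walking the descending ranking, the sum gains `|stat|^w / Σ|stat|^w` at set
members and loses `1/(N − N_hit)` elsewhere; the enrichment score (ES) is
the signed extreme and the leading edge is the members at or before
(positive ES) / at or after (negative ES) the extreme.  Choices:

* weight `w = 1` (the classic preranked default of the tool family the
  screen used); `w = 0` gives the rank-only statistic.
* gene-label permutation (the only option for preranked input):
  NES = ES / mean(|null ES| of the same sign); p uses the add-one estimator
  `(1 + #{null at least as extreme, same sign}) / (1 + #same sign)`, so
  p ≥ 1/(n_perm + 1).  This is a deliberate simplification of the
  multilevel split-sampling estimator used by fgsea-style implementations:
  it is exact to analyze, fully deterministic given a seed, and adequate
  when the smallest p of interest is ~1e-4.
* ranking ties are broken by gene id; an exact tie between the positive and
  negative extreme (measure-zero for continuous statistics) resolves
  positive, with a 1e-12 tolerance so floating-point noise cannot flip the
  sign.
* set-size bounds 10–500 after intersection with the ranked universe;
  skipped sets are reported with a reason, never silently dropped.

Null calibration (permutation p uniform by KS test) and equivalence to a
step-by-step prefix-sum oracle are both asserted in the suite.

## Disease-signature concordance and reversal

The disease side is the same enrichment run on a postmortem meta-analysis
effect vector (per-protein disease effect), mapped into the knockdown
gene space through an explicit ortholog table; one-to-many ortholog pairs
are dropped and counted.  Three comparisons follow:

* **Zero-imputed NES pairs + Kendall.** The union of terms significant
  (adjusted p ≤ 0.05) in either analysis is paired term-by-term; a term
  non-significant or absent on one side contributes NES 0 there.  Within
  each biological domain, Kendall's tau-b (tie-aware — zero imputation
  creates ties by construction) is computed over the paired NES, BH runs
  across all (target, cell line, domain) tests in the run, and a
  significant negative tau is labeled a **reversal**, positive
  **concordant**.  Domains with fewer than 5 pairs or a constant side are
  reported untested and excluded from the BH family (rank correlations on
  tiny n are uninformative; a constant side is usually an all-zero imputed
  perturbation, i.e. no evidence at all).
* **Protein-level Pearson.** Proteins are grouped into domains by
  annotation to any domain term; per (target, cell line, domain) the
  knockdown log2FCs are correlated with the orthologous disease effects
  (minimum 10 proteins).
* **Quadrant counts.** Per domain, terms are classified by the sign pattern
  of (perturbation NES, disease NES); zeros count as one-sided.

## Integration and top-tier calls

Assay effect sizes (the mixed-model marginal means) are correlated with
term NES across (target, cell line) points using Spearman's rho per
(assay, term), BH across all pairs.  LPS-induced NFkB effects are excluded
before pairing because proteomes were collected without LPS induction.
Terms absent from a knockdown's enrichment output are dropped from that
pairing (inner join; zero-imputation is specific to the disease
comparison), with a 10-observation minimum.

The top-tier rule is explicit and configurable because the underlying
screen states the outcome, not a formula: by default a target is top-tier
iff it has ≥ 1 assay hit in any cell line AND ≥ 1 domain labeled a
reversal in any cell line.  The reversal-direction requirement reflects
the screen's emphasis on disease-signature reversal; `require_reversal_
direction: false` relaxes the proteomic side to any significant domain
correlation, and a domain whitelist can restrict the evidence base.
Tightening any rule parameter can only shrink the top-tier set.

## The synthetic reference study

The generator produces every input with known truth.  Defaults define the
reference study: 12 targets (3 planted dual-evidence, 2 assay-only, 7
null), 2 cell lines, 4 assays (the NFkB reporter at 2 LPS doses), 2,000
proteins, 100 terms over 6 domains (~200 genes per domain pool), with the
screen's replication structure (3–7 batches of 3–5 replicates per assay;
~5 proteome replicates per siRNA and cell line).

* **Assay readouts**: `baseline × 2^effect × 2^batch × 2^noise` with batch
  intercepts ~ N(0, 0.25²) shared by all conditions in a batch and
  lognormal measurement noise (σ = 0.2 on the log2 scale) — matching the
  log2FC analysis model.  Planted assay effects are ±1 log2 unit,
  amplified 1.5× in the sensitized line (the Psen2-knockdown motif).
* **Disease effects**: genes of two disease-up domains get mean +1, two
  disease-down domains mean −1, others 0, plus N(0, 0.5²) heterogeneity.
* **Reversal knockdowns** shift each gene of their planted domains by
  −0.8 × that gene's disease effect plus N(0, 0.3²).  The mirroring is the
  point: a constant per-domain offset would flip signs but carry no
  term-to-term rank signal, whereas mirroring makes the per-domain NES
  rank correlation genuinely negative — which is what "signature reversal"
  means operationally.  Every knockdown additionally lowers its own
  protein by 1.5 log2 units.
* **Missingness** is completely at random at 10% (an intensity-dependent
  option exists, default off, since the emulated analysis handles
  missingness only by sample exclusion), plus two planted low-quality
  samples at 75% dropout for the QC filter to catch.  The bundled run
  config scales the QC threshold to this 2,000-protein world (1,600).
* **qPCR** Ct tables encode a 70% knockdown with GAPDH-style reference
  normalization and 0.15-cycle noise.

Proteome-only distractors (reversal without assay effects) are supported
(`n_proteome_only`) but default to zero.  This is a designed property of
the reference study: with BH at 0.05 and several strong true hits per
12-target family, each null target carries a ~2% per-family false-hit
probability, so a target whose only missing evidence is phenotypic would
turn into a false top-tier call in a substantial fraction of runs — not
because the pipeline errs, but because the rule's phenotypic arm is an
α-level test.  Exact zero-false-positive recovery is therefore expected
only when reversal evidence is confined to targets with real assay
effects; the proteome-only configuration remains available for studying
exactly that failure mode.

What the generator does **not** emulate: plate/spatial effects beyond
batch intercepts, intensity-dependent (MNAR) missingness in the default,
correlated protein co-expression within domains beyond the planted
shifts, ontology structure among terms (terms are flat, disjointly
domain-assigned by default), and any raw-spectra or imaging level of the
assays.  Passing tests therefore demonstrate correctness of the
statistical machinery and end-to-end recovery under the assumed generative
model, not robustness to those real-data complications.

## Numerical and design notes

* All randomness flows from one seed through named child streams
  (annotation, disease, orthologs, proteome, assays, qPCR), so any stage
  is reproducible independently of the others; same seed ⇒ byte-identical
  files.
* BH adjustment delegates to statsmodels and is verified against a literal
  step-up implementation; Kendall/Spearman/Pearson delegate to scipy and
  are verified against O(n²) pair counting, rank-then-Pearson, and the
  covariance formula respectively.
* Run-scale permutation count is 10,000; the reference-study config uses
  999 (problem sizes chosen to keep a complete end-to-end analysis around
  a minute on one CPU: 25 enrichment runs × 100 sets, ~46,000 Tukey
  contrasts, 5 mixed-model fits).
* Gene identifiers are case-sensitive opaque strings end to end; the only
  cross-species join is the explicit ortholog table.

## Known limitations

* The normal-reference Wald test is mildly anti-conservative at very small
  batch counts; the t switch exists but no Satterthwaite approximation.
* Tukey HSD assumes homoscedastic groups within a protein; no Welch-type
  variant.
* The Kendall BH family spans one run; cross-run meta-analysis (e.g.
  combining cell lines) is deliberately out of scope.
* The add-one permutation p floors at 1/(n_perm+1); deeply significant
  sets saturate there and are distinguished by NES, not p.
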