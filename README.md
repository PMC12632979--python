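# targetscreen

Integrated phenotypic + proteomic screening of candidate therapeutic
targets.

## The problem

Genetic and omics studies nominate far more candidate disease genes than
can be taken into drug development.  A practical filter is functional: knock
each candidate down in a disease-relevant cell system, ask (a) whether the
perturbation moves cellular phenotypes that matter (viability,
mitochondrial membrane potential, phagocytosis, NFkB signaling), and (b)
whether the proteomic response moves disease-associated biology — ideally
*against* its disease direction.  `targetscreen` implements the statistics
of such a screen end to end, for analysts running siRNA perturbation panels
in paired cell backgrounds (e.g. a control line and a sensitized
Psen2-knockdown microglial line) with replicate assay readouts and
DIA-style proteome quantification.

## What it computes

* **Knockdown QC** — relative expression by the 2^−ΔΔCt method and percent
  knockdown efficiency from qPCR Ct tables.
* **Phenotypic hit calling** — per-batch log2 fold changes
  (target vs control siRNA within batch, cell line, and LPS dose), a
  random-intercept linear mixed model per assay
  (`log2FC ~ siRNA × cell line + (1 | batch)`, REML), Wald tests of the
  marginal means, Benjamini–Hochberg adjustment, hits at adjusted p ≤ 0.05.
* **Differential protein abundance** — sample QC (exclude samples below a
  quantified-protein floor), then per-protein one-way ANOVA across siRNA
  groups with Tukey HSD adjusted target-vs-control contrasts, per cell
  line, with nan-aware complete-case handling.
* **Preranked GSEA** — the weighted Kolmogorov–Smirnov running-sum ES,
  gene-label permutation NES and p, BH across sets, with every gene set
  annotated to biological domains (e.g. Immune Response, Mitochondrial
  Metabolism).
* **Disease-signature concordance** — per-domain Kendall tau-b between
  zero-imputed NES signatures of a knockdown and of the disease
  (postmortem meta-analysis effects through an ortholog map), per-domain
  protein-level Pearson correlation, and sign-quadrant term counts.  A
  significantly negative domain correlation is a **reversal**: the
  knockdown pushes that domain's biology against its disease direction.
* **Integration** — Spearman correlation of assay effect sizes with term
  NES across knockdowns (LPS-induced NFkB excluded), and a configurable
  **top-tier** rule: a target with at least one assay hit *and* at least
  one reversal domain.

A first-class synthetic-data generator produces every input with planted
ground truth (batch structure, cell-line sensitization, domain-coherent
reversals, DIA-like missingness), which is how the pipeline validates
itself: on the default seeded study it must recover exactly the planted
dual-evidence targets.

## Worked example

Run the complete reference study (12 targets, 2 cell lines, 4 assays,
2,000 proteins, 100 terms over 6 domains, 3 planted dual-evidence targets):

```
targetscreen run-all --out-dir run --seed 0
```

`run/results/verdicts.tsv` then contains (first rows):

```
target  n_assay_hits  n_reversal_domains                         reversal_domains  top_tier
   T01            10                   2 Immune Response;Mitochondrial Metabolism      True
   T02            10                   2 Immune Response;Mitochondrial Metabolism      True
   T03            10                   2 Immune Response;Mitochondrial Metabolism      True
   T04            10                   0                                               False
   T05            10                   0                                               False
   T06             1                   0                                               False
```

T01–T03 are the planted dual-evidence targets: each is a hit in all ten
assay × cell-line × dose strata and reverses both planted domains, so each
is called top-tier.  T04/T05 carry planted assay effects but no proteomic
reversal — hits, not top-tier.  T06's single hit is an α-level false
positive that the dual-evidence rule absorbs.  `run/results/
knockdown_efficiency.tsv` shows the qPCR side (the generator plants 70%
knockdown):

```
gene  n_replicates  mean_fold_change  knockdown_pct
 T01             3          0.295449      70.455066
 T02             3          0.266208      73.379167
```

The same stages are available as library calls (`targetscreen.analyze_assays`,
`targetscreen.differential_abundance`, `targetscreen.enrich_collection`,
`targetscreen.call_top_tier`, ...) and as per-stage subcommands
(`simulate`, `kd-qc`, `phenotypes`, `proteomics-de`, `enrich`,
`concordance`, `integrate`) that communicate through plain TSV/CSV files.

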