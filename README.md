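# cftme

Analysis of tumor-microenvironment (TME) transcriptional archetypes from
pre-treatment plasma **cell-free RNA (cfRNA)** in CAR-T–treated lymphoma
cohorts — for computational biologists working with liquid-biopsy RNA-seq
count data who want the full analysis chain as a tested, reusable library
rather than a one-off notebook.

The pipeline answers three questions about a gene-by-sample count matrix
with responder / non-responder labels and progression-free survival (PFS):

1. **Do TME archetype signatures appear in plasma?** Per-sample module
   scores for the LN (lymph-node-like), FMAC (follicular
   macrophage/accessory cell) and TEX (T-cell-exhausted) archetype marker
   sets, computed as the mean log2-CPM of the 20 marker genes minus the
   mean of an expression-matched random control set (100 controls per
   target gene, drawn from 25 expression bins), min-max rescaled to [0, 1]:

       score_j = mean_{g in targets} x_gj − mean_{g in controls} x_gj

2. **Do they stratify outcome?** Median split of the module score into
   high/low, Kaplan-Meier curves, log-rank test, and a univariate Cox
   model (Breslow ties) with a Wald test.

3. **Do they predict response?** Monte Carlo cross-validation (101
   iterations of stratified 70/30 splits) of L1-penalized logistic
   regression, with the penalty chosen per split by stratified 5-fold CV
   maximizing held-out AUC; AUC distributions per feature set and
   feature-recurrence (selection-frequency) tables across iterations.

Around these sit sample QC on summary metrics (intron/exon ratio > 3,
5′/3′ bias > mean + 3 SD, depth < 100k), TMM/log2-CPM normalization,
pseudobulk aggregation of labeled single-cell counts, a
discovery/validation differential-abundance analysis with
Benjamini-Hochberg control and cross-cohort Pearson concordance of log2
fold changes, and a negative-binomial synthetic cohort generator that makes
the whole chain testable without any external data. See
`docs/methods.md` for models, assumptions, and design decisions.

## Worked example

Simulate a three-cohort study (28/28/35 samples, 2,000 genes) with a
log2FC = 1.2 effect on the 20 LN-analog marker genes in responders, then
run each stage:

```bash
cat > sim.yaml <<EOF
effect_log2fc: {LN: 1.2, FMAC: 0.0, TEX: 0.0}
qc_fail_fraction: 0.05
EOF
cftme simulate --config sim.yaml --seed 7 --outdir .
cftme qc --metadata metadata.tsv --outdir .
cftme normalize --counts counts.tsv --outdir .
cftme score --counts counts.tsv --gmt analogs.gmt --seed 7 --outdir .
cftme survival --scores module_scores.tsv --metadata metadata.tsv --score-column LN_scaled --outdir .
cftme cv --logcpm logcpm.tsv --metadata metadata.tsv --feature-set LN --gmt analogs.gmt --iterations 101 --seed 7 --outdir .
cftme differential --counts counts.tsv --metadata metadata.tsv --outdir .
```

prints

```
wrote 2000 genes x 91 samples to .
85 of 91 samples pass QC
normalized 1969 genes x 91 samples
scored 3 gene sets over 91 samples
log-rank p = 0.0666; Cox Wald p = 0.06951
median test AUC = 1.000 over 101 iterations
Pearson r = 0.505 over 17 discovery-significant genes
```

Reading these numbers: 5 of the 6 injected QC failures plus one borderline
library are removed (85/91 pass); 31 genes were never observed and are
dropped before normalization. The planted LN effect is large relative to
the negative-binomial noise, so the 20-gene LN feature set separates
responders essentially perfectly in held-out test sets (median AUC 1.0).
Outcome stratification is weaker — survival here depends on responder
status (log hazard ratio −0.7), which the median-split LN score tracks
only imperfectly, giving a borderline log-rank p ≈ 0.07 at n = 85. The
differential stage has the least power: with only two discovery cohorts
(56 samples) and a BH threshold of 0.1, 17 genes reach significance and
their fold changes correlate at r ≈ 0.5 with the held-out cohort —
cross-cohort concordance needs either stronger effects or more samples,
which is exactly what the acceptance experiments use.

(`analogs.gmt` maps the LN/FMAC/TEX names onto the simulator's gene
identifiers; with real data you would instead use the packaged 20-gene
archetype marker lists, `cftme.archetype_gene_sets()`.)

The same stages run end-to-end with one config via `cftme run` +
`cftme report`, which write a manifest with per-stage checksums for
reproducibility.

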