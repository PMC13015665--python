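# Methods

`cftme` implements a pre-treatment plasma cell-free RNA (cfRNA) analysis of
tumor-microenvironment (TME) transcriptional archetypes in patients
receiving CAR-T therapy: quality filtering of cfRNA libraries, TMM/log2-CPM
quantification, expression-level-controlled archetype module scores,
survival stratification, Monte Carlo cross-validated sparse classification
of treatment response, and cross-cohort differential-abundance concordance.
This note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Sample quality filtering

Libraries are filtered on three precomputed summary metrics, never on the
counts themselves:

- **DNA contamination** — intron-to-exon read ratio strictly greater than 3
  (`QCThresholds.max_intron_exon_ratio`).
- **RNA degradation** — 5′/3′ coverage bias strictly greater than the
  reference-group mean plus 3 standard deviations
  (`bias_sd_multiplier`). The mean and SD are frozen on the pre-filter
  distribution and applied in a single pass; there is no iterative
  re-computation. The reference group defaults to the full analyzed sample
  set (`bias_reference_group="all"`), with a per-cohort option. A single
  pooled reference is the default because at roughly 30 samples per cohort
  the pooled moment estimates are markedly stabler.
- **Depth** — strictly fewer than 100,000 feature-aligned reads
  (`min_total_counts`).

All inequalities are strict; a sample exactly at a cutoff is retained. A
discarded sample carries every reason code that applies
(`dna_contamination`, `rna_degradation`, `low_depth`).

Note the arithmetic of the degradation rule: with a single outlier among
`n` samples the largest attainable z-score is `(n−1)/√n`, so the 3-SD rule
cannot flag anything in groups of ten or fewer — a real property of the
rule, not a bug, and the reason the packaged tests exercise it at n ≥ 12.

## Normalization

Between-sample scaling uses the trimmed mean of M-values (TMM). For each
sample against a reference (the sample whose 75th-percentile count fraction
is closest to the mean), per-gene log ratios `M = log2((c_gj/N_j)/(c_gr/N_r))`
and abundances `A = ½·log2((c_gj/N_j)(c_gr/N_r))` are formed over genes
positive in both samples, doubly trimmed (30% of M and 5% of A from each
tail, by rank), and averaged with weights equal to the inverse asymptotic
binomial variance of M. Factors are rescaled to geometric mean 1. These
constants follow the method's original definition and are exposed in
`NormalizationConfig`. The implementation agrees with Bioconductor edgeR's
`calcNormFactors(method="TMM")` to about 1e-6 on test fixtures, and with an
independent brute-force script to 1e-10.

Gene abundance is quantified as
`log2-CPM = log2((c + p) / (N_j·f_j) · 1e6)` with pseudocount `p = 0.5`
added to the counts and the TMM-adjusted effective library in the
denominator. The pseudocount/prior-count dialect of logCPM varies between
tools; this simple closed form was chosen for exact testability and is a
config knob. Genes with zero counts in all samples are dropped before TMM
and scoring: they carry no information and have undefined M/A values.

`NormalizedMatrix` retains `N_j`, `f_j` and `p`, so the count>0 detection
indicator can be recovered exactly from the log2-CPM matrix (each sample's
zero-count value is known in closed form). The Monte Carlo CV stage uses
this for its per-iteration detection filter.

Pseudobulk profiles are per-sample × per-cluster sums of single-cell
counts (columns named `sample|cluster`). A cluster is flagged for exclusion
from cell-type-specific analyses when it has fewer than 10 cells in more
than 3 samples; the flag is reported, not silently applied, and the
boundary (exactly 3 deficient samples) retains the cluster. Cluster labels
are inputs; no clustering is performed here.

PCA diagnostics (`select_variable_genes`, `pca_embed`) rank genes by
log2-CPM variance (top 500 by default, ties broken by identifier) and embed
samples by SVD of the per-gene-centered matrix, with the sign convention
that each component's largest-magnitude gene loading is positive.

## Archetype module scores

The central statistic. Three 20-gene marker sets — LN (lymph-node-like),
FMAC (follicular macrophage/accessory cell), TEX (T-cell-exhausted) — ship
with the package as a GMT file. One printed source of the FMAC list
contains the token "CLEC14 CD36" with a missing delimiter; the packaged set
treats these as the two genes CLEC14 and CD36, which is what makes the set
20 genes long. Swapping in a corrected identifier is a one-line GMT edit.

Scoring controls for expression level in the style of Tirosh et al.'s
single-cell signature scoring:

1. Genes are ranked by mean log2-CPM across samples and cut into 25
   equal-frequency bins (rank-based bins avoid empty bins; ties break by
   gene identifier).
2. For each target gene, 100 control genes are drawn uniformly from that
   gene's bin — without replacement when the bin is large enough, with
   replacement otherwise. Target genes remain eligible as controls, and
   one control multiset is drawn per target set (not per sample), fully
   determined by the seed and recorded in an audit manifest.
3. The raw per-sample score is the mean log2-CPM over target genes minus
   the mean over the control multiset. It is invariant to adding any
   per-sample constant, and has expectation 0 when targets and controls
   are exchangeable.
4. Raw scores are min-max rescaled to [0, 1] within the analyzed sample
   set. A constant score vector (undefined min-max) maps to 0.5 with a
   warning. Rescaling per cohort is available by scoring cohorts
   separately.

Target genes absent from the matrix are dropped with a warning and listed
in the manifest — cfRNA matrices routinely miss genes — and excluding
targets from the control pool is left off by default (a sensitivity knob).

## Outcome analysis

Two-group comparisons use the two-sided Mann-Whitney U test: exact
enumeration when `n1·n2 ≤ 64` with no ties, otherwise the normal
approximation with tie and continuity corrections (scipy).

Survival stratification follows the module-score figure convention:
samples strictly above the median score are "high", those at or below are
"low" (ties deliberately go low, matching the asymmetric above/below-median
wording). Kaplan-Meier curves and the log-rank test come from lifelines.
The Wald test is a univariate Cox proportional-hazards model on the
high/low indicator, fit by Newton-Raphson on the partial likelihood with
Breslow tie handling (convergence: |score| < 1e-8, max 50 iterations).
Breslow was chosen over Efron so a grid-search oracle over the partial
likelihood can verify the fit exactly; the continuous-score Cox model is
also available. Monotone likelihoods (covariate perfectly ordering the
risk) are detected by coefficient divergence and raised, not silently
reported with a huge standard error.

## Predictive modeling

Monte Carlo cross-validation with 101 iterations per feature set (all
transcripts, LN, FMAC, TEX). Each iteration:

1. stratified 70/30 train/test split (round-half-up per class; both classes
   must appear in both partitions);
2. λ selected on the training set by stratified 5-fold CV maximizing mean
   held-out AUC, ties toward the larger λ (the sparser model);
3. refit of an L1-penalized logistic model on the full training set;
4. test AUC (Mann-Whitney formulation, ties ½), the selected λ, and all
   non-zero coefficients recorded.

The loss is mean negative log-likelihood plus `λ·Σ|βk|` with an unpenalized
intercept; the solver is scikit-learn's liblinear with `C = 1/(n·λ)` and a
large intercept scaling so the intercept is effectively unpenalized
(residual intercept shrinkage is below 1e-2 on the tested fixtures; KKT
residuals below 1e-4). Inner-CV fits, which only rank λ values, use a loose
solver tolerance (1e-4); the recorded refit uses 1e-8. Features are
standardized with training-fold statistics only. The λ grid defaults to 30
log-spaced values over [1e-3, 1e2] and is config-exposed, as are the
standardization and inner objective, since none of these is uniquely
canonical.

For the all-transcripts set, features must be detected (count > 0) in at
least 25% of the iteration's training samples — computed per iteration from
the training partition via the detection mask, so there is no test leakage.

Per-iteration RNG substreams are keyed by `(seed, iteration)`, so results
are bit-reproducible and independent of execution order. Feature
recurrence reports, per feature, the fraction of valid iterations with a
non-zero coefficient plus the coefficient median, IQR and sign consistency.

## Differential abundance and concordance

The discovery/validation design is preserved exactly: two cohorts discover,
the third validates. Per gene, the log2 fold change is the difference of
group means on the log2-CPM scale (responders minus non-responders) — a
deliberately simple estimator chosen for exact oracle testability; it is
*not* DESeq2's shrunken negative-binomial estimator, and the per-gene test
is the package-default Mann-Whitney U rather than a Wald test on GLM
coefficients. This module is documented as a stand-in for that machinery:
the design (discovery BH threshold 0.1, inner join on gene identifier,
Pearson correlation of discovery-significant fold changes against
independent validation estimates) is the analysis of interest, not the GLM
internals. All-tied genes get p = 1 with a degeneracy flag. BH adjustment
is the standard step-up procedure (statsmodels).

## Synthetic cohort generator

The generator is first-class, tested code and defines the study conditions
for every calibration and recovery experiment:

- **Counts**: negative binomial with mean `lib_j · q_g · 2^(β_g·r_j)` and
  variance `μ + φμ²` (the standard RNA-seq count model; the mean/dispersion
  parameterization is fixed). `q_g` ~ Gamma(shape 0.4, rate 0.004) gives a
  heavy-tailed abundance profile (mean ≈ 100 counts/gene, many
  near-silent genes, as in cfRNA); `lib_j` is log-normal (σ = 0.4);
  `r_j` is the responder indicator; `β_g` is the configured log2 effect on
  marker genes and 0 elsewhere. Default dispersion φ = 0.3 reflects the
  high biological variability of patient plasma samples.
- **Design**: three cohorts of 28/28/35 samples; responder fraction 0.5
  per cohort (per-cohort responder fractions are not asserted anywhere and
  are configurable); alternating leukapheresis / pre-lymphodepletion
  timepoints.
- **Survival**: exponential event times with hazard `h0·exp(log_hr·x)`
  (`h0 = 0.05`/month, censoring at 24 months); the covariate may be a
  binary group or a continuous score. Responders default to log HR −0.7
  (better progression-free survival).
- **QC failures**: injected by overwriting metric fields only (ratio 5,
  bias 5, or depth 50,000, cycling), never by altering counts — mirroring
  the fact that the filters consume summary metrics.
- **Single cell**: Poisson counts per cell (~1,000 counts/cell) with
  sample and cluster labels; the per-sample×cluster cell layout can be an
  explicit matrix so tests can plant deficient clusters.
- **Determinism**: one integer seed; every operation draws from its own
  deterministically derived substream, so outputs are byte-identical under
  a fixed config.

What the generator does *not* emulate: gene-gene correlation, cohort batch
effects, compositional coupling between markers and background, GC/length
biases, and fragment-level artifacts. Passing recovery tests therefore
demonstrates that the statistical machinery is correct and calibrated under
the assumed generative model, not that effect sizes of any particular
magnitude are detectable in real plasma.

## Problem sizes in the test suite

The calibration and recovery experiments run at deliberately chosen sizes:
scoring recovery at 100 replicates of 60 samples × 1,000 genes; CV recovery
at 101 iterations on the 20-gene LN set (signal and label-permuted); feature
recurrence at 20 replicates of 101 iterations with 3 planted genes among
1,000 (for that experiment the baseline abundance is Gamma(2, 0.02), since
an effect planted on a near-silent gene is unrecoverable by any method and
the experiment probes selection, not detection limits); concordance at
2,000 genes with 200 non-null effects and 30 samples per cohort; Cox
recovery at n = 500 with a true hazard ratio of 2.

## Known limitations

- The differential module's estimator and test are stand-ins, not a
  negative-binomial GLM; counts with strong mean-variance coupling will
  give different (unshrunken) fold-change estimates than DESeq2.
- The Cox model is univariate; no adjustment for clinical covariates.
- liblinear's intercept handling is approximate (see above); coefficients
  are reported on the standardized scale.
- Min-max rescaled module scores are dataset-relative: scores are not
  comparable across separately rescaled datasets.
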