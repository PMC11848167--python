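# Methods

## Study design being emulated

The pipeline reproduces the stage structure of a sex-stratified single-cell
case–control study of Alzheimer's disease: an aged post-mortem cortex cohort
divided into controls and three Braak-staged AD groups with sex-stratified
sizes (at full scale 146 controls = 72 M + 74 F, 19 early, 59 intermediate
and 82 late AD, 306 subjects in total), annotated cell types, and clinical
covariates (age, Braak stage, MMSE, with MMSE below 20 for patients and in
[20, 30] for controls). Because such cohorts are restricted-access, the
package analyses synthetic data whose planted structure is recorded and used
as ground truth; the generators are part of the tested surface, not
fixtures.

## Synthetic data generator

Counts are negative-binomial with log link: gene × cell-type baseline means
are drawn log-uniformly over [0.05, 5] counts/cell (planted genes over
[0.5, 2], a moderate-expression band appropriate for genes whose
differential expression is the object of study), scaled by lognormal
per-cell size factors (σ = 0.3) and, for AD cells of sex *s*, by
`exp(direction_s · Δ)` for each planted effect. Dispersion is a parameter:
0 gives Poisson data (the regime in which the differential-expression model
is correctly specified, used for calibration and recovery runs); the
pipeline default of 0.15 adds realistic overdispersion and exercises the
model's robustness. Effect directions encode the category semantics
(neutral: same nonzero direction in both sexes; specific: nonzero in one
sex, zero in the other; dimorphic: opposite). The per-subject cell count is
a parameter (default 50) since atlas-scale per-subject depth varies widely.

Deliberately not simulated: ambient RNA, doublets, batch effects, and
gene–gene correlation beyond the planted regulatory chain. Passing recovery
tests therefore demonstrates correctness of the statistical machinery under
the generative model, not robustness to those artefacts.

Two interactions between the generator and the analysis are worth knowing:

* **Composition effects.** Size factors are per-cell totals over the
  stratum median. If a large fraction of the transcriptome is planted
  up-regulated, AD totals shift and null genes acquire a spurious opposite
  signal. Recovery runs therefore use a transcriptome-scale gene count
  (2,000 genes, 40 planted ⇒ ≈1% composition shift, immaterial); the
  toy-scale demo (500 genes) accepts a small residual.
* **The specificity guard is itself stochastic.** A planted sex-specific
  gene is classified `ambiguous` whenever the *other* sex's null nominal p
  happens to fall below 0.1 (≈10% of genes by uniformity). Per-category
  recovery therefore has expectation ≈9/10 and pooled recovery ≈93%; this
  is a property of the classification rule, not an implementation defect.

## Differential expression

Poisson GLM likelihood-ratio test per gene within each (cell type, sex)
stratum. For the two-group design with offsets, the MLE rates are the group
count totals over group exposure totals, so the deviance is evaluated in
closed form and referred to χ²(1); a generic-optimizer refit is kept as an
independent oracle in the tests. Size factors enter as log offsets
(total-count/median; zero-total cells get factor 1). Genes expressed in
fewer than `min_pct` (default 0.1) of cells in both conditions are excluded
before testing; BH correction spans the tested genes of the stratum.
All-zero rows return the degenerate (p = 1, deviance 0).

Log fold changes are natural-log ratios of mean normalized expression with
a pseudocount of 0.01. The pseudocount is small because normalized means
live on the raw-count scale (≈0.1–5): a unit pseudocount there would shrink
a true ln-FC of 0.8 to roughly half and silently defeat the 0.25
effect-size floor for low-expression genes, while 0.01 only guards the
one-sided-zero case. Subject identity is not modelled (cells are treated as
independent within a stratum, as per-cell GLM testing does); this
pseudoreplication caveat applies to any per-cell test and is the main
reason the covariate module aggregates to pseudobulk instead.

## Sex-pattern classification

Applied rules, in order, with significance := adjusted p < `fdr` (0.05) and
|ln FC| > `min_lfc` (0.25, applied to the significant sex only): both
significant & same sign → neutral; both & opposite → dimorphic; exactly one
& other nominal p > `nonsig_p` (0.1) → that sex's specific category;
exactly one & other p ≤ 0.1 → ambiguous; neither → not significant. The
explicit `ambiguous` bucket keeps the partition exhaustive and testable; a
gene untested in one sex (expression filter) is likewise ambiguous —
absence of a test is not evidence of non-significance. Dimorphic calls
require the effect-size floor in both sexes, since each sex must be
independently significant.

## Enrichment

Exact hypergeometric upper tail (no normal approximation) of a query list
against each gene set, after intersecting sets with the universe and
keeping sizes in [5, 500]. The universe is the stratum's *tested* genes —
conditioning on testability avoids detection-bias inflation; it is a
parameter. BH across tested sets. Term-level sex specificity reuses the
gene-level rule (adjusted p < 0.05 in one sex, nominal p > 0.1 in the
other); communication enrichment filters at *nominal* p < 0.05, the
convention of that stage.

## Cell–cell communication

Sender/receiver expression filters are strict (> 10% of cells nonzero).
Candidate ligand–receptor pairs must be expressed on both ends and touch at
least one DEG of the requested category. Ligands are ranked by the number
of DEGs reachable from them by directed paths in the prior network — a
deliberately transparent influence score standing in for regression-based
ligand-activity models that belong to external tools; top 30 are reported
by default.

## GRN construction

Prior interactions are kept only with mechanisms in {binding, transcription
regulation, influence on expression, co-regulation of transcription,
regulation} and brain tissue; self-loops and duplicate (source, target,
sign) rows are dropped. Boolean states: B_AD(g) = 1 iff ln FC(g) > 0,
B_CTRL = 1 − B_AD (networks are built over DEGs, so states are defined and
complementary by construction — which also makes per-edge consistency
identical in the two phenotypes). Consistency semantics: activation ⇒ equal
endpoint states, inhibition ⇒ opposite. Fitness of an edge selection is the
fraction of (target, phenotype) pairs explained by ≥ 1 consistent selected
incoming edge, minus λ·(selected/candidate); λ = 0.01 breaks ties toward
parsimony, so fitness ∈ [−λ, 1]. The GA chromosome is one inclusion bit per
edge plus one sign bit per unknown-sign edge (joint optimization of
selection and sign inference); tournament selection (k = 3), uniform
crossover (0.9), per-bit mutation (1/L), elitism 2, population 200, up to
500 generations with a 50-generation stagnation stop, all reproducible from
the seed. Tests hold the GA to the exhaustive optimum on ≤12-bit instances
(with a reduced population/generation budget suited to those sizes) and to
a greedy marginal-gain baseline.

Perturbagen score: number of nodes reachable downstream (full reachability,
not direct targets — influence propagates; a direct-only variant is a
one-line restriction). Mediator score: |ancestors| × |descendants|, ranking
nodes that both aggregate upstream changes and broadcast downstream; the
top node is the key mediator, and its ancestor-closure subnetwork can be
exported as SIF/DOT for upstream-regulator views.

## Proteomics

Per protein and sex: OLS of abundance on intercept + condition + age at
death, complete-case within the row, minimum 3 samples per condition;
collinear age is dropped with a warning. Variance moderation follows the
scaled-inverse-χ² empirical-Bayes scheme with hyperparameters from the
method of moments on log s² (excess variance of log s² beyond trigamma(df/2)
inverts to d0; the mean locates s0²); posterior variances are the
df-weighted blend and the moderated t has df + d0 degrees of freedom
(normal reference when d0 = ∞; identical observed variances short-circuit
to complete pooling). d0 = 0 reproduces ordinary t-tests exactly, which the
tests assert. Protein classification reuses the gene rule with effect sign
in the ln-FC role and no effect-size floor (abundance units are not fold
changes); the cross-omics intersection is per cell type × category with
unmapped identifiers reported, never dropped.

## Covariate correlations

Per-subject pseudobulk (mean size-factor-normalized expression over the
subject's cells of one type, subjects with < 3 cells dropped) avoids
pseudoreplicating per-cell values against per-subject covariates. Spearman
rho uses mid-ranks; p-values use the t approximation with n − 2 df (exact
permutation available for n ≤ 10). Braak is ordinal 0–6; controls carry no
stage and are excluded from Braak correlations. BH within each
covariate × sex block.

## Pipeline and reproducibility

`run_pipeline` executes simulate → DE per sex → classify → enrich → comm →
GRN → proteomics → intersect → correlate from a single validated config
(YAML-loadable; invalid thresholds fail before any stage runs). Every
output TSV carries a provenance header (tool version, config hash, seed)
and the run writes a manifest with per-file SHA-256 checksums; reruns with
the same config are byte-identical. Stage seeds are fixed offsets from the
config seed.

## Problem sizes

Defaults are chosen so the full demo runs in seconds and the test suite in
well under a minute of compute: toy pipeline at 96 subjects × 50 cells ×
500 genes; calibration at 2,000 null genes × 200 cells/condition; recovery
at 2,000 genes with 500 cells per (sex, condition) stratum; moderation
recovery at 5,000 simulated variances; GA oracle checks on 20 instances of
≤ 12 chromosome bits.

## Known limitations

* Per-cell GLM testing ignores subject-level correlation (no random
  effects); with many cells per subject this overstates confidence, which
  is why covariate analyses use pseudobulk.
* The Poisson model is knowingly thinner-tailed than the negative-binomial
  generator default; calibration guarantees hold at dispersion 0.
* The ligand-influence score is reachability-based plumbing, not a learned
  ligand-activity model.
* The GA objective is the simplest Boolean-alignment criterion consistent
  with "explained by a consistent incoming edge"; other published network
  construction objectives differ in detail.
* No GO-DAG redundancy trimming, ranked GSEA, batch correction, or
  peptide-level proteomics processing.
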