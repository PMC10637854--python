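# Methods

## Overview

`adors` implements an oligogenic risk score for Alzheimer's disease
(AD) built in three stages: (1) common variants are collapsed into
per-gene, direction-corrected burdens; (2) the gene set is condensed
by ranking burdens on their Pearson correlation with two PET
endophenotypes (FDG-PET SUVR, a hypometabolism marker, and AV45-PET
SUVR, an amyloid marker); (3) a logistic model on the selected burdens
(adjusted for age and sex, optionally an APOE allele score) supplies
the weights of the score. Comparators — a clumping+thresholding (C+T)
polygenic risk score and an APOE ε2/ε4 allele score — and an
evaluation layer (AUROC/AUPRC with cross-validation, decile
stratification, cognitive-phenotype association, exact Shapley
contributions) complete the package.

## Labels

Longitudinal visit diagnoses over {CN, EMCI, LMCI, AD} are collapsed
into one cross-sectional label. Under both policies a sample whose AD
diagnosis is not maintained once reached (a relapse) is excluded, and:

* `CN` — every visit CN; `MCI_nc` — every visit EMCI/LMCI;
* `MCI_c` — first visit EMCI/LMCI, last visit AD (maintained);
* `AD` — policy `text`: every visit AD; policy `table1`: first visit
  CN or AD and last visit AD, so CN-first converters count as AD.

The two policies exist because the natural-language and tabular
definitions of the AD group in the source cohort literature are not
reconcilable; they provably differ only on CN-first converters (an
exhaustive truth-table test asserts this). Default is `text`; under it
the CN-vs-AD task counts MCI converters as cases ("consistently AD or
MCI-c"), under `table1` it does not. Neither is asserted to be the
ground truth of any external dataset.

## Gene burdens

For variant k with effect-allele dosage x_ik ∈ {0,1,2}, the
direction-corrected dosage is

    s_ik = 2 − x_ik   if the variant's GWAS log-odds β_k < 0
    s_ik = x_ik       otherwise (β_k = 0 takes the identity branch)

and the burden of gene j is v_ij = Σ_{k ∈ g_j} s_ik over QC-passing
biallelic variants that (a) fall in the gene's interval and (b) appear
in the summary statistics — a direction requires a GWAS sign. The
complement keeps protective and risk effects from cancelling within a
gene. Variants inside overlapping genes contribute to every containing
gene (interval semantics of refGene-style annotation). Missing dosages
are mean-imputed per variant using training-split samples only
(policy `mean`, default) or propagate as missing (policy `drop`).

## Gene selection

For each biomarker, genes are ranked by the Pearson correlation of
burden with the biomarker, computed on the training split only by
default (`full_cohort` mode exists for parity with analyses that do
not hold out data). The top k = 20 per biomarker are pooled; the union
(≤ 40, typically high-30s because the two rankings overlap) is the
oligogenic gene set G. Ranking uses |r| by default: FDG hypometabolism
falls with AD risk while amyloid load rises, so the two biomarkers
plausibly correlate with a risk gene in opposite directions and
magnitude is the defensible rank statistic; `signed_r` mode is
provided. Ties break lexicographically by gene symbol, constant
burdens are ineligible (undefined correlation is an error signal,
never silently zero), and no multiple-testing calibration is applied —
selection is purely rank-based.

## Risk model and score

A maximum-likelihood logistic model is fitted per task (CN-vs-AD or
MCI conversion) on the burdens of G plus age (years, uncentered) and
sex (0 female / 1 male), optionally plus the APOE score. Burdens enter
raw — the score is defined on raw burden units — with a
standardization switch. The oligogenic score is the gene part only:

    adORS_i = Σ_{j ∈ G} β_j v_ij

(no intercept, no covariate terms; the full linear predictor is
reported alongside). Development uses a stratified 80:20 train/test
split and stratified 10-fold cross-validation inside the training
split; the split is fixed up front and shared by imputation,
selection, fitting and the Shapley reference so the 20% test split is
never touched before evaluation. Both the split and fold assignment
derive from the configured seed (default 0) and are recorded in the
model metadata.

If the ML fit fails to converge or shows numerically unbounded
standardized coefficients (|β|·sd > 50), separation is assumed and the
model is refitted with an L2 penalty (strength 1.0 on standardized
features, configurable), mapping coefficients back to the raw scale;
a warning is emitted and the fallback is flagged on the model.

## APOE allele score

APOE is handled outside the genome-wide scores (its region,
chr19:44.0–46.0 Mb on GRCh38, is excluded from both the PRS and the
burden gene set) and modeled as a weighted allele count,
β(ε2)·#ε2 + β(ε4)·#ε4 with shipped external-GWAS weights
β(ε2) = −0.47 and β(ε4) = 1.12.

## PRS comparator

C+T in the narrated order: APOE-region removal → greedy clumping →
p-thresholding. Clumping sorts by ascending p (ties by chromosome,
position), takes the best unclaimed variant as index, and removes
unclaimed variants on the same chromosome within ±1000 kb whose
squared Pearson dosage correlation with the index exceeds 0.1, with r²
estimated on the analysis cohort itself (pairwise-complete dosages).
The shipped threshold grid is {5e-8, 1e-5, 0.1, 0.5} with primary
threshold 1e-5. The score is Σ_k β_k x_ik over retained variants,
sharing the burden module's train-mean imputation. At synthetic-cohort
scale (a replicate association study of n ≈ 1000, versus the
tens-of-thousands scale of a real consortium GWAS) per-variant tests
have essentially no power at 1e-5, so desk-scale runs and the
acceptance script use the lenient end of the grid; the shipped default
remains 1e-5.

## Interpretation

For an additive model the Shapley value of feature j for sample i has
the closed form φ_ij = β_j (x_ij − mean_ref(x_j)) under a
feature-independent (mean-substitution) value function; the package
uses this exact form on the log-odds scale, with the training split as
the reference set. Tests verify equality with full 2^p coalition
enumeration and local accuracy φ_0 + Σ_j φ_ij = linear predictor for
every sample. For the PRS, variant contributions β_k x_ik are pooled
per gene; each retained variant lands in exactly one bucket (its first
containing gene in sorted order, else the intergenic pseudo-gene) so
the buckets partition the score exactly. Contribution shares are
mean-|φ| percentages (summing to 100); the per-feature direction is
the sign of corr(feature value, φ). Probability-scale attribution is
deliberately out of scope — the closed form is exact only on the
linear-predictor scale.

## Stratification

Samples are stably sorted by score (ties by sample ID) into 10 bins;
with n = 10q + r the first r bins (low-score end — an arbitrary but
fixed convention) hold q+1 samples. The staircase statistic is the
Spearman correlation between bin index and case count; all-equal
counts return 0 by convention with a warning. Deciles are computed on
the held-out test split by default.

## Quality control

Variant-level filters, in order: per-call masking (GQ < 20 or DP < 10
becomes missing, when the fields exist), missing rate > 20%,
monomorphism, exact Hardy–Weinberg test p < 1e-6. The HWE test is the
exact conditional test: given allele counts, the heterozygote count is
summed over all tables with probability ≤ the observed one (plain
two-sided, no mid-p; computed in log-space with a 1e-12 relative tie
slack). HWE uses all samples — restricting to controls is a known
variant of the filter but is not the default here. Sample-level QC
(relatedness, contamination, sex checks) requires raw sequencing
artifacts and is an upstream assumption, not part of this package.

## Synthetic cohorts

The generator emulates the joint structure every stage assumes:
binomial(2, MAF) dosages with MAF ~ U(0.05, 0.5) for ~200 genes of
5–15 variants (plus intergenic variants); 10 causal genes whose
direction-corrected burdens (variant signs Rademacher) drive a shared
signal entering both PET biomarkers (FDG negatively, AV45 positively;
effect 0.3 per burden unit with noise sd 0.6, giving per-gene
population correlations near 0.3) and the liability (effect 0.25,
noise sd 1.5), alongside an APOE allele-score term, small age/sex
terms, and Gaussian noise; case status by liability threshold at the
configured prevalence (0.5); cognitive scores loaded on standardized
liability with the clinical sign pattern (ADAS13/CDRSB/FAQ up,
MMSE/RAVLT down; loading 0.6, noise 0.8, 2% missingness); visit
sequences consistent with case status (an `mci_fraction` switch puts
samples on converter/non-converter tracks). Summary statistics are
estimated on an independent replicate cohort drawn from the same truth
— mimicking the external-GWAS assumption of a PRS and avoiding
circularity — via vectorized per-variant linear (score-test)
regression of case status on dosage; downstream only consumes the
sign and the p-value ranking.

What the generator does **not** emulate: genome-wide LD structure
(variants are independent given the truth), population
structure/admixture, rare variants, genotyping batch effects, or
realistic visit-interval censoring. Passing recovery tests therefore
demonstrates correctness of the machinery under the stated model, not
expected performance on real cohorts.

## Problem sizes and numerical choices

Simulation-based tests use 20 replicates of n = 1000 samples × 200
genes (10 causal) for the recovery bands (selection recall ≥ 0.8 mean,
held-out adORS AUROC ≥ 0.65 mean against a null band of 0.42–0.58,
staircase ≥ 0.8 mean), sizes chosen to finish a full suite run in
about a minute while keeping estimator noise well inside the bands.
The acceptance script averages 10 replicates per condition. Exact
primitives (burdens, Shapley, clumping, AUROC, HWE) are tested against
independent brute-force oracles at exact or 1e-10/1e-12 tolerance.

Determinism: every stochastic step (simulation, splits, folds) is
driven by explicit seeds; selection, clumping and decile assignment
define total orders via documented tie-breaks, so identical inputs and
config reproduce identical outputs byte for byte.

## Known limitations

* Burdens collapse functional and nonfunctional variants alike; no
  consequence weighting (deliberately out of scope).
* Within-gene direction consistency is assumed by construction of the
  complement operation; opposing true effects within a gene still
  dilute the burden.
* The cohort itself serves as the LD reference for clumping; with an
  external panel results would differ.
* Only two endophenotypes guide selection; genes tied to other AD
  biomarkers are invisible to the score.
* No imputation from reference panels, no liftover, no multi-allelic
  decomposition (drop-and-report only).
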