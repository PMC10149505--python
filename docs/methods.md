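# Methods

This note documents the models, estimators and numerical choices behind
`omicscreen`, the assumptions each stage makes, and what the synthetic
cohort does and does not emulate.

## Cohort design and the synthetic generator

The package targets a two-group panel of patient-derived primary cell
models: 10 benign (BPH) and 25 tumor models by default, with 29 of them
(10 + 19) entering the drug screen. The generator
(`omicscreen.simulate`) produces every input layer with a planted,
machine-readable ground truth (`CohortTruth`), which is what makes the
downstream estimators testable.

**Proteome.** Per-protein log2 intensities are Gaussian around a
log-normal baseline (mean log2 intensity ~ N(20, 1.5)), with additive
per-sample loading offsets (sd 0.25), per-protein × batch effects
(sd 0.15, four TMT-style batches) and residual noise (default sd 0.5,
log2). Each batch carries one pooled internal-reference channel whose
expected intensity is the across-sample mean of the cohort; the channel
shares its batch's effect, so the sample/reference ratio cancels it —
the reason internal-reference normalization is used at all. Differential
features (default 5% of proteins, |log2 FC| = 1, both directions) are
shifted in tumor samples.

**Surfaceome.** Two label-free runs per sample with independent noise
(sd 0.6, log2) and missing-not-at-random dropout: the missingness
probability is logistic in log2 intensity (midpoint 21, scale 1.2), so
dimmer proteins vanish more often. This is the stress test for the run
merging rule and the <50% / <20% missingness filters.

**Transcriptome.** Negative-binomial counts (gamma–Poisson, dispersion
0.1) whose log-means share the protein layer's per-sample deviations plus
independent noise calibrated so the per-gene mRNA–protein correlation is
~0.3 by construction; counts are also reported as TPM under equal
effective lengths. The empirical median Spearman comes out somewhat above
the 0.3 target because the top-SD gene filter preferentially retains
planted differential genes, whose shared group effect correlates across
layers — the same selection effect one expects in real data.

**Drug screen.** True response curves are three-parameter log-logistic
with slope b ~ U(0.7, 2), floor c ~ U(0, 0.25) and cell-specific
log10 inflection (drug-level mean, cell scatter sd 0.4). Doses are seven
10-fold dilutions from 10 µM; treatments are in triplicate with 5%
multiplicative signal noise; six DMSO wells set the baseline and three
near-zero wells emulate the total-kill positive control. Selective drugs
(default 5) have the tumor group's log10 inflection shifted down by 1
(more sensitive); coupled protein–drug pairs (default 5) make log10(e) a
linear function of the planted protein's log2 abundance, which induces a
known-sign Spearman association with the resistance score.

**Variants and survival.** Per-sample variant counts are Poisson (means
50 tumor / 6 benign) over a fixed classification vocabulary; four planted
genes recur in ~60% of tumor samples to exercise the top-mutated-gene
ranking. Survival times are exponential with a group hazard ratio and
independent exponential censoring.

What the generator does **not** emulate: peptide-level quantification and
protein inference, ragged batch layouts, correlated protein modules,
nonlinear mean–variance trends in RNA counts, plate position effects, or
informative censoring. Passing tests therefore demonstrate correctness of
the estimators under a clean generative model, not robustness to every
artifact of real acquisitions.

## Preprocessing

*Median normalization* rescales each sample so its median matches the
median of the original per-sample medians — the grand-median target keeps
the output on the raw intensity scale (the alternative, scaling medians
to 1, loses interpretability). The operation is idempotent to 1e−12.

*Reference ratios*: each value becomes log2(sample / in-batch reference);
reference columns are dropped afterwards. A missing (or non-positive)
reference value propagates missingness to its whole batch for that
feature, which is the conservative choice.

*QC*: Hartigan's dip statistic is computed per sample with the classic
iterative greatest-convex-minorant / least-concave-majorant algorithm.
p-values are calibrated by bootstrap from the uniform distribution
(default 1000 resamples, seeded; the null is cached per sample size).
The uniform is the stochastically largest unimodal null, so the test is
conservative for normal-ish data — in 100 replicate normal samples of
n = 1000 it essentially never rejects. The QC gate is: every dip p > 0.05
and every reference-pair Pearson r ≥ 0.97 (configurable).

*Run merging* is cellwise mean / retained-unique / missing, and is
symmetric in its arguments. *KNN imputation* first drops features with a
missing fraction ≥ 0.2, then fills each hole with the unweighted mean of
the k nearest features under nan-Euclidean distance (computed over
co-observed samples and rescaled by the number shared); observed values
are never altered. When fewer complete neighbor features exist than k,
all available ones are used with a warning.

## Differential expression and integration

The per-feature test is the two-sided Wilcoxon rank-sum: exact
enumeration when the combined sample size is ≤ 20 and tie-free, otherwise
the tie-corrected normal approximation. No continuity correction is
applied in the asymptotic branch: at the panel's group sizes (10 vs 25)
the correction makes the test conservative enough that the empirical
type-I error falls detectably below nominal, breaking p-value
calibration; without it the rejection rate at α = 0.05 is 0.050 over
50 000 null features. Features with fewer than two observed values per
group are reported with NA p-values rather than silently dropped.

Fold changes are tumor/BPH ratios of geometric means on log2-scale layers
(equivalently, back-transformed differences of log2 means) and ratios of
arithmetic means on TPM. Direction calls require both p < α and the
layer's fold-change gate (1.2 for proteome and surfaceome, 1.5 for RNA);
no multiple-testing correction is applied by default, matching the raw-p
convention of the workflow, with a BH switch in the config.

Cross-layer overlap counts partition genes by the exact set of layers in
which they pass their gates. Fold-change concordance excludes features
non-significant in the proteome before correlating log2 fold changes
(Pearson). The CRG set is the union of the multi-omics overlap genes and
the top mutated genes, with overlap taking provenance precedence.

Spearman correlation uses average ranks; for n ≤ 9 the p-value is exact
by enumerating all rank permutations, otherwise the t approximation with
n − 2 df. Constant inputs return NA with a reason code.

## Enrichment

Preranked GSEA with gene-set permutation: the enrichment score is the
signed extremum of a running sum that rises by |score|^w (normalized over
in-set genes; w = 1 by default, w = 0 classic) at hits and falls by
1/(N − |S|) at misses. For each observed set, the null is the ES of
random same-size gene sets drawn from the ranked list (nulls are shared
across sets of equal size). NES divides ES by the mean |null ES| of
matching sign; the p-value is the doubled matching-sign tail (with the
+1 correction), so 1000 permutations resolve p down to ~0.004; FDR is
Benjamini–Hochberg across sets — simpler and better-defined than the
NES-pooling FDR of the original tool, and all that is needed for an
FDR < 0.05 gate. The default two-group ranking metric is
sign(log2FC) × −log10(p).

## Dose–response

The viability model is Log-logistic with the upper asymptote fixed at 1
(untreated viability after DMSO normalization), free slope b ∈ [0.05, 20],
floor c ∈ [0, 1] and inflection e ∈ [min dose/100, max dose×100], fitted
by bounded trust-region least squares from a 5 × 2 multi-start grid over
(e, b). IC50 is the absolute dose where the fitted curve crosses 0.5,
closed-form d = e·((1−c)/(0.5−c) − 1)^(1/b); it is censored when c ≥ 0.5,
when the curve stays above 0.5 at the top dose, or when the crossing lies
beyond it. Under the acceptance conditions (7 doses, 5% noise) the median
|Δlog10 IC50| is ≈ 0.04.

The activity area is the discrete sum over tested doses of
(1 − viability) clipped to [0, 1] — the robust convention that needs no
fit — and 7-AA is defined as 7 − AA, a resistance-oriented score (larger
= less sensitive). This orientation is the one that makes a *positive*
protein–drug correlation mean "more protein, more resistant", which is
the only reading self-consistent with a sensitizing knockdown; the
alternative reading is available via `aa_orientation: activity` in the
config. The identity aa + seven_aa = n_doses is exact by construction.
Drug selectivity is the pooled-variance two-sided t-test on 7-AA between
groups.

## Pharmacoproteome

Proteins missing in ≥ 50% of the screened cells are removed, then each
remaining protein × drug pair is Spearman-correlated over its
pairwise-complete cells (minimum 5; the global filter does not say how
residual holes are handled, so pairwise-complete is used). Coefficients
with p ≥ 0.05 are reset to missing — the delivered rho matrix shows
significant associations only — while the unmasked matrix is retained for
diagnostics. A fully observed panel takes a vectorized rank-correlation
path; panels with holes fall back to per-pair computation, and the two
paths agree to 1e−9. No multiple-testing correction by default (raw
p < 0.05 convention), with a BH option. CRG–drug summaries count, per
drug, the CRGs with unmasked positive/negative coefficients; CRG genes
absent from the protein matrix are reported as unmapped rather than
erroring.

## Synergy

The combination index inverts each single-agent fit at the observed
combined effect E = 1 − viability using the closed form
D(E) = e·((1−c)/(1−E−c) − 1)^(1/b), guarded as E approaches the maximal
achievable effect 1 − c (undefined CI with a reason, never an abort
inside a grid). Sham combinations give CI = 1 to machine precision, and
CI is invariant to swapping drug labels with their doses. Qualitative
calls use CI < 0.9 synergy / > 1.1 antagonism; the thresholds are
configurable since no canonical cutoff exists.

## Variants and survival

Variant summaries are exact tallies; the top-mutated ranking orders by
patients affected, then total mutations, then gene symbol. The log-rank
test is implemented directly (hypergeometric variance at each event time,
chi-square with groups − 1 df) so the per-group observed/expected table
is part of the result; it matches `lifelines` to nine digits in tests.
Median splits assign values equal to the median to "low". Cox
proportional-hazards estimation is deliberately out of scope; group
comparisons are log-rank only.

## Problem sizes and runtime

The shipped tests and the acceptance script run the generator at reduced
feature counts (hundreds to a thousand proteins rather than the ~7000 of
a full panel) — the estimators are dimension-wise independent, so feature
count affects only runtime, not calibration. Monte-Carlo sizes follow the
stated acceptance conditions: 200 curves for IC50 recovery, 100 panels
for coupling-sign recovery, 50 × 1000 features for rank-sum calibration,
500/200 replicates for log-rank size and power, 1000 gene-set
permutations. The DE recovery check plants differential features in 20%
of proteins so the false-discovery proportion is estimated from a stable
number of calls; the cohort default remains 5%.

## Known limitations

- The dip-test p-value is calibrated against the uniform null only; it is
  a QC gate, not a general-purpose modality test.
- The exact Spearman branch enumerates permutations and is limited to
  n ≤ 9 by design.
- IC50 values are absolute (curve crosses 0.5), so panels with shallow
  curves or high floors produce censored entries that drop out of
  rank-correlation summaries.
- The Loewe inversion assumes the fitted [0,1]-bounded log-logistic is
  correct for both agents; model misfit propagates directly into CI.
- TPM in the generator assumes equal effective transcript lengths.
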