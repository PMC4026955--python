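# Methods

This note records the statistical conventions the package implements, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical choices made where the design was
genuinely open.

## Data model

A cohort is a subjects × loci matrix of genotype codes 0/1/2 (copies of the
*control-minor* allele; −1 = missing) with per-subject phenotype, sex, and
asthma-subtype labels.  Orientation is always recomputed from the data: after
reading any file, code 2 counts the allele that is minor among controls, with
ties (frequency exactly 0.5) keeping the file's orientation.  Deletion-type
polymorphisms (expressor vs. null alleles, where the assay cannot see
heterozygotes) use codes 0 and 2 only; every 2×3 procedure drops genotype
classes that are empty in the pooled margin and adjusts its degrees of
freedom, so the empty middle class is handled uniformly rather than as a
special case.

Missing genotypes are handled by pairwise-complete deletion throughout: a
subject is excluded only from computations that involve its missing loci.
No imputation is performed.

Stratification follows case-control practice for subtype analyses: a sex
filter applies to everyone, a subtype filter applies to cases only — the
controls are the comparison group of every subtype stratum.

## Contingency statistics

* **HWE χ²**: expected counts np², 2npq, nq² from the sample allele
  frequency; df = 1; no continuity correction; undefined (error) for a
  monomorphic sample.
* **2×3 genotype association**: Pearson χ² (scipy), df = retained classes − 1.
* **2×2 with conditional corrections**: when any *observed* cell is below the
  small-cell threshold (default 10), the χ² uses the Yates continuity
  correction n(|ad−bc|−n/2)²/((a+b)(c+d)(a+c)(b+d)) (floored at 0) and the
  odds ratio adds 0.5 to all four cells (Haldane–Anscombe) before the
  cross-product; otherwise both are uncorrected.  The 95% CI is Woolf's
  interval exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)) on the possibly corrected
  cells.  This conditional rule reproduces, at printed precision, every χ²
  and OR of the reference study's two-locus combination tables — both the
  corrected small-cell rows and the uncorrected rows with all cells ≥ 10 —
  and is exposed as a configurable threshold.  The OR is computed as the
  cross-product ratio rather than by an iterative logistic fit; for a single
  binary predictor the two coincide.
* **Bonferroni**: min(1, m·p) with m always supplied by the caller per
  analysis family, never a global constant — the reference analyses use
  different m per table and stratum.

## Set association analysis

Per-marker statistic s_i = χ²(2×3 association), optionally multiplied by the
case-group HWD χ² (`stat_mode="product"`, the default).  Markers whose
*control-group* HWD χ² is ≥ 6.6 (the 99th percentile of χ² with df 1) are
trimmed before ranking; trimming is decided once, on the observed controls,
and the permutation replicates recompute s_i and the ranked sums over the
fixed untrimmed set (a per-replicate trim would change the sum length across
replicates).

The remaining markers are ranked by decreasing s_i (ties by panel order),
S_n is the sum of the top n, and each S_n receives a permutation p-value by
shuffling case/control labels and recomputing everything per replicate; all
permutation p-values in the package use the add-one estimator
(r + 1)/(N + 1).  The global significance of p_min = min_n p_n is computed
from the same replicate ensemble: each replicate's own p-curve is evaluated
against the full ensemble and its minimum forms the null for the observed
p_min.  This single-ensemble shortcut avoids nested permutations and is
validated empirically (type-I error 0.05–0.06 at the 5% level over 200 null
cohorts; KS uniformity not rejected at α = 0.01).

**n\* tie-break.**  With strong effects every S_n can sit at the permutation
resolution floor (p_n = 1/(N+1) for all n), making argmin ties universal.
Among tied minimal-p sums the scan selects the n whose S_n exceeds its own
permutation distribution by the most standard deviations (ties then to the
smaller n).  Under the null, ties at the minimum are rare and the rule is
inert; with planted effects it recovers the size of the causal set (the
recovery experiment selects n\* = 3 for three planted loci in ≥ 88% of
replicates).

The recovery experiment itself uses `stat_mode="association_only"`: a
multiplicative per-allele risk model keeps case genotypes in Hardy-Weinberg
proportions, so the case-HWD factor contributes no signal to the ranking and
only noise.  Both statistic modes share all plumbing and are recorded in
every output.

## Multifactor dimensionality reduction

Cells of the multilocus genotype grid are labeled high-risk when the
training-set case:control ratio of the cell reaches the threshold (default:
the overall training case:control ratio; equality counts as high risk; cells
with cases but no controls are high risk; empty cells default to low risk so
every subject is classifiable — `unclassified` is available and then excluded
from accuracy denominators).  Accuracy is *balanced* accuracy (mean of
sensitivity and specificity; raw accuracy available), so
prediction error = 100·(1 − balanced test accuracy) exactly.

Evaluation uses stratified 10-fold cross-validation repeated over shuffle
seeds (default 10).  In a search, the combination with the best *training*
accuracy in a fold is "selected" for that fold; CVC is the percentage of
folds selecting a combination, averaged over seeds.  The best model per
order maximizes mean CVC (ties: mean test accuracy, then lexicographic locus
order).  Forced search restricts enumeration to a caller-given locus pool.
Significance is a Monte-Carlo permutation test: labels are permuted, the
search re-run at the model's order, and the best permuted test accuracy
compared with the observed one; p = (r+1)/(N+1).  With 999 permutations the
achievable floor is exactly 0.001, which a purely epistatic XOR pair
(penetrances 0.9/0.1 at MAF 0.5, 400 cases / 400 controls) reaches while
being selected with CVC 100%.

How the reference analysis aggregated CVC across seeds (mean vs. best seed)
and whether its prediction error used balanced or raw accuracy are not
derivable from the printed values; the package defaults to the mean and to
balanced accuracy and exposes both choices.

## Interaction entropy

Plug-in (maximum-likelihood) entropy estimates, base-2 logs, no bias
correction: at the cohort sizes involved (≥ 130 subjects per stratum) the
plug-in bias of the interaction gain is well below the reported effects (the
null check at n = 10 000 bounds |IG| < 0.002 bits).  IG pairs are classified
by |IG|/H(Y) with defaults 0.02 (strong) and 0.005 (weak), both
configurable, and the classifier is monotone in IG.  The dendrogram uses
average linkage on D(A,B) = max IG − IG(A,B) — deterministic given the locus
order, no inversions — and is emitted as Newick text plus a class-annotated
edge table.  The reference figures' exact normalization and linkage are not
stated; both choices are surfaced in output metadata.

## Two-locus combination scan

For each locus pair in the pool and each of the 3×3 genotype-code pairs, the
subjects carrying exactly that combination are contrasted against all other
subjects with both genotypes observed (carrier-vs-rest; this construction
matches the printed Ns and percentages of the reference tables exactly).
Zero-carrier combinations are skipped and excluded from the Bonferroni
multiplier, which is always reported (`m_tests`) so any adjustment
convention can be audited.

## Synthetic cohorts

The generator samples retrospectively: subjects are drawn from a prospective
penetrance model (genotypes from HWE proportions per locus, disease from the
multilocus penetrance, optional per-sex penetrance scaling) and rejected
until per-group quotas are filled — by default the reference design's
strata: allergic 64 M / 92 F, nonallergic 29 M / 27 F, 3 cases of unknown
subtype, controls 105 M / 109 F.  Odds ratios, not risk ratios, are
therefore the recoverable effect measure.  Hardy-Weinberg disequilibrium is
injected as an additive perturbation of the heterozygote probability
(renormalized), the simplest one-parameter control of control-HWD trimming.
The default 46-locus panel cycles the 21 control minor-allele frequencies
printed in the study's allele-frequency table, so synthetic cohorts share
the study's frequency spectrum.

The XOR model is the classic checkerboard: elevated penetrance iff exactly
one of the two loci is heterozygous.  At MAF 0.5 both single-locus marginal
penetrances equal the mean penetrance exactly, giving a purely epistatic
effect with no marginal signal.  Loci are simulated independently: linkage
disequilibrium, population stratification, and covariates beyond sex are out
of scope, so passing tests demonstrate correctness of the machinery, not
robustness to confounding structure real panels may carry.

## Problem sizes of the validation experiments

Chosen once as the experiments' study conditions: SAA null calibration —
200 cohorts of 200/200 subjects × 20 loci (MAF 0.3), 500 permutations each;
SAA recovery — 50 cohorts of 500/500 with 3 multiplicative loci (GRR 2.0)
among 20; MDR oracle equivalence — 500 random instances of ≤ 3 loci and
≤ 30 subjects against a per-cell enumeration oracle; MDR XOR recovery —
400/400 subjects on a 6-locus panel, 999 permutations; MDR null calibration
— 200 cohorts of 100/100 × 4 loci at 100 permutations; entropy null bound —
n = 10 000.

## Known limitations

* The reference study's SAA global p-values, MDR CVC / prediction-error
  table, and dendrogram topologies depend on unpublished subject-level
  genotypes and cannot be recomputed; only its printed aggregate statistics
  are reproduced, and the stochastic machinery is validated on synthetic
  ground truth instead.
* Printed p-values in the combination tables are internally inconsistent
  with their own χ² in several rows and are therefore derived from χ²
  rather than asserted against the print.
* Exact (Fisher) tests, covariate-adjusted regression, trend tests,
  haplotype analysis, and ≥ 3-locus genotype combinations are out of scope.
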