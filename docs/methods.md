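# Methods

## Data model

Genotypes are stored as a subjects × SNPs integer matrix with the
additive coding 1/2/3 (wild-type homozygote / heterozygote / variant
homozygote) and 0 as the missing-call sentinel (written `.` in text
formats). The sentinel choice makes corrupt data detectable: every
valid cell is one of four values. Labels are binary, case = 1 /
control = 0, aligned to subject identifiers.

Two genotype orientations coexist deliberately. The simulator defines
code 3 as the homozygote of the minor allele (the frequency `q` it
draws), which removes strand ambiguity and gives planted effects a
closed-form expected score. VCF import instead maps code 3 to the ALT
homozygote regardless of which allele is minor, because that convention
is reproducible without estimating frequencies. MeanDiff and the
squared Euclidean distance are unaffected in ranking by a global 1↔3
flip of a SNP only up to magnitude, so the conventions are fixed and
documented rather than auto-detected.

## Synthetic cohort generator

The generator emulates a genotyped case-control cohort at the level
the pipeline can see: class balance, per-SNP allele-frequency spectrum,
HWE-consistent genotypes, and a minority of SNPs carrying either signal
or QC violations.

* Null SNP at frequency `q`: genotypes drawn i.i.d. per subject from
  the HWE proportions `((1−q)², 2q(1−q), q²)`, identically in cases and
  controls. `q` is uniform over `maf_range` (default 0.05–0.5, the
  post-QC spectrum).
* Effect SNP: controls keep `q`; cases use `q + effect_delta`, capped
  at 0.999 to keep probabilities valid, each group in HWE internally.
  The additive effect on the allele scale was chosen because the
  expected MeanDiff then has the closed form `2·|q_case − q_control|`
  (expected code is `1 + 2q` under HWE), giving parameter-recovery
  tests an exact oracle.
* HWE-violating SNP: all subjects drawn from Wright's inbreeding
  distortion `((1−q)² + Fq(1−q), 2q(1−q)(1−F), q² + Fq(1−q))`.
* Low-MAF SNP: a null SNP at `low_maf_value` (default 0.01).
* Missing-call SNP: each call independently replaced by the sentinel
  with probability `missing_rate`; at least one call is forced missing
  so the planted set is exactly the set with missing data.

Defaults are 302 cases / 321 controls (the class balance of the kind of
discovery cohort the pipeline targets) and 10,000 SNPs — a desk-scale
panel chosen so default runs finish in seconds; real cohorts are ~50×
wider, which changes runtime but not the statistical structure any
stage depends on. All planted counts default to zero.

What the generator does **not** emulate: linkage disequilibrium
(every SNP independent), population structure and admixture,
genotyping-batch artefacts, and covariates. Passing tests therefore
demonstrate correctness of the algorithms and their calibration under
independence, not robustness to the correlation structure of real
genomes — with LD, nearby SNPs would enter the top-m panel in blocks
and nested-LOOCV variance would be larger than the binomial bands used
here.

## Quality control

The three filters run in one pass over the original matrix (no
re-estimation after removals) and are adjudicated independently,
except that a SNP with any missing call fails on missingness alone —
its MAF/HWE statistics are still computed on the available calls, but
only as diagnostics.

* Missingness: any missing call removes the SNP (absolute).
* HWE: Pearson chi-square with 1 df on observed genotype counts in
  **controls** against expectations at the estimated allele frequency;
  removal at p < `hwe_alpha` (default 0.001). The chi-square was chosen
  over the exact test as the conventional closed-form default; at the
  panel sizes used here (n ≥ a few hundred, MAF ≥ 5%) its false-removal
  rate calibrates to the nominal level (verified at n = 2000).
  Monomorphic columns return chi² = 0, p = 1 by convention.
* MAF: allele count of the rarer allele over 2 × called subjects,
  computed over **all** subjects (common GWAS practice; whether the
  original analyses used all subjects or controls only is not
  documented, so the choice is fixed here and exposed as a parameter).
  Removal at MAF < `maf_min` (default 0.05), strict: exactly 5%
  survives. The boundary convention is configurable (`maf_strict`).

An empty surviving panel raises a dedicated error rather than passing
an empty matrix downstream.

## Feature selection and classifier

MeanDiff is computed in floating point from small-integer rational
means; exact float equality is therefore meaningful and is used for
tie detection. Ties at the selection boundary break by ascending SNP
index — determinism across platforms was preferred over randomised
tie-breaking.

KNN distances are computed in exact int64 arithmetic (the expansion
`|p|² + |q|² − 2p·q` on integer codes), so distance ties are exact.
Tie-breaks are: k-th-neighbour distance ties by ascending training
index (exactly k neighbours always vote); vote ties toward the
training-set majority class, and toward control if the training set is
itself balanced. With binary labels and odd k the vote tie-break never
fires, but the contract is total. No distance weighting is applied.

## BestKNN

Internal folds are class-stratified with seeded shuffling (per-class
fold sizes differ by at most one). Stratification is a design choice:
the internal CV operates on small complements where unstratified folds
risk class imbalance or emptiness; the seed is recorded in the trace.
Within each fold, the top-m panel is recomputed on the fold complement
only; the per-fold panel generally differs between folds, which is the
leakage-avoidance property the procedure exists for. The chosen k is
the high-watermark of mean fold accuracy, smallest k on ties (simplest
model preference, deterministic). The final model refits on all
training data with a fresh full-data selection. The trace retains all
|k_grid| × r fold accuracies; requires each class ≥ r.

## Evaluation

* `nested_loocv`: for each subject, all of BestKNN (selection +
  k-choice) reruns on the other N−1 subjects; per-subject sub-seeds are
  derived from the master seed via a seed sequence, so runs are
  bit-reproducible and independent of evaluation order. The per-fold
  log records the chosen k and SNP panel, which is what the leakage
  tests instrument.
* `biased_loocv`: the top-m panel is selected once on the full data;
  the loop then runs the identical machinery restricted to that fixed
  panel (per-fold k-selection retained). The single difference from
  nested mode is the selection leakage, so the accuracy difference
  isolates that effect. Results carry `mode="biased"` and the report
  prints a warning.
* Metrics: accuracy (tp+tn)/N, precision tp/(tp+fp), sensitivity
  tp/(tp+fn), specificity tn/(tn+fp); undefined ratios are NaN, never
  silently 0. Percentages round half-up to 2 dp for reports; raw
  proportions are kept in machine output.
* Permutation test: B label permutations (class counts preserved), the
  full nested pipeline per permutation, p = (x+1)/(B+1) with ties
  counted as exceedances. The add-one estimator is never zero and at
  B = 100 with zero exceedances gives p = 1/101 < 0.01; the
  uncorrected x/B would claim p = 0.
* `m_sweep` reruns nested LOOCV across panel sizes (default
  500–1500 by 100) for sensitivity analysis.

## Problem sizes in tests and the acceptance script

Statistical checks run at sizes where the tested property has clear
power but the whole suite stays fast: QC calibration at 2,000 subjects
× 20,000 SNPs (null MAF range 0.10–0.5 there, so sampling noise cannot
carry a null SNP across the 5% boundary — at q = 0.1, n = 2000 the MAF
standard error is ≈0.0034); LOOCV calibration at 120 subjects ×
~1,000 SNPs; the selection-bias demonstration at 100 subjects × 10,000
SNPs with m = 500 (the regime where leakage is most dramatic);
permutation runs at 40 subjects with B = 19 or B = 100. Null-regime
accuracy bands are binomial: ±4 standard errors around 0.5.

## Known limitations

* LOOCV on balanced null data is slightly pessimistic (removing a
  subject leaves their class one short in training), so null accuracies
  sit a little below 50% on average; the test bands account for this.
* The HWE chi-square is anticonservative for very rare alleles; the
  MAF filter removes that regime before it matters in the pipeline, but
  `hwe_test` applied alone to rare-allele columns inherits the usual
  small-expected-count caveat.
* No subject-level QC, no population-stratification correction, no
  X-chromosome handling: inputs are assumed to be a stratification-
  corrected autosomal genotype matrix.
* The whitelist option restricts candidates to a user-supplied SNP set;
  curated disease-specific panels are the user's responsibility.
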