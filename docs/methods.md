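# Methods

## Scope and model

caseforge implements a case-augmentation pipeline for biobank-style data:
a balanced gradient-boosted ensemble learns a per-disease biomarker
signature from diagnosed cases and matched controls, scores the whole
population, and promotes high-probability participants into nested
augmented case cohorts on which rare-variant collapsing tests are re-run.
The core fitted object follows the Model/Results convention:
`DiseaseSignatureModel(features, cohort, config).fit()` returns a
`DiseaseSignatureResults` with cross-validated metrics, feature
importances, population predictions and a `summary()` table.

## Cohort definition

* Cases: union over all diagnosis sources and all hierarchy descendants
  of the queried ICD10 code; one record per participant, keeping the
  diagnosis with the shortest absolute time-lag. Eligibility requires
  ≥ 100 cases.
* Time-lag: (diagnosis − collection) in days / 365, rounded to the
  closest integer, half away from zero (the rounding convention is a
  package choice; only "closest integer" is prescribed by the method).
  Lag 0 belongs to both the prognostic [0, t] and diagnostic [−t, 0]
  windows, both inclusive; t defaults to 10 years.
* Sex filter: when one sex holds > 0.9 of cases, minority-sex cases are
  dropped. The 0.9 threshold is applied directly to every phenotype.
* Controls: participants with no diagnosis in the case code's ICD10
  chapter. Age is binned at the quartile edges of the *case* age
  distribution (the binning basis is a package choice); within each
  (bin × sex) cell, `ctrl_ratio` controls per case are sampled without
  replacement, with `ctrl_ratio` the largest integer ≤ `ctrl_ratio_max`
  that every cell can supply. Cases in cells whose supply cannot cover
  them are dropped. Sampling is a seeded permutation over id-sorted
  candidates, so ties are reproducible.

## Ensemble

* Learner: XGBoost (`tree_method="hist"`, single thread, library-default
  depth 6 and learning rate 0.3); only `n_estimators` is tuned, over
  {50, 100, 200, 300}, by fitting on one balanced case/control set and
  scoring AUROC on that same set (apparent AUROC — deliberately, to match
  the method; `tune_cv=True` offers honest 3-fold tuning). Ties go to the
  smallest tree count.
* Balanced ensemble: per replicate (10) and CV fold (5), fold-training
  controls are partitioned into `ctrl_ratio` near-equal disjoint
  subsamples; one classifier per subsample trains on fold cases plus that
  subsample. Fold metrics average over subsample models, replicate
  metrics over folds, and the reported performance is the median over
  replicates. Sensitivity/specificity use a 0.5 probability threshold
  (configurable; the source method does not state its threshold).
* Population predictions: one full-data classifier per replicate; the
  prediction table is the mean probability over replicates.
* FIS: per-submodel gain importances normalized to sum 1, averaged over
  all submodels (plain mean; the per-tree weighting inside the gain
  measure is xgboost's standard definition). FIZ: z-scores of the log of
  the nonzero FIS values using the population SD (n-denominator); the
  closed form for the pattern (a, b, b) then puts the top feature at
  z = √2 ≈ 1.414 exactly, above the 1.2 dominating-feature threshold.
  z-scores are invariant to the logarithm base.
* Seed schedule: one root seed; every stage (tuning subsample, replicate
  control draw, fold shuffle, each submodel) derives a 31-bit child seed
  by SHA-256 hashing of the stage path, so runs are bit-reproducible and
  stages are independent.

## Preprocessing

Imputation → one-hot encoding → standardization, all statistics fitted on
training rows only. Special rules: rheumatoid factor imputes to 0 IU/ml
and oestradiol to 36.71 / 110.13 pmol/l (men / women) because missingness
in these assays means "below detection", not "not measured"; testosterone
imputes sex-specific training medians. Standardization uses the
population SD (n-denominator — the sample/population choice is not
prescribed; n was chosen and is consistent with the FIZ convention);
zero-variance features map to zero columns, unseen categories to all-zero
blocks. Shadow-feature (Boruta-style) selection for wide feature sets
appends a permuted copy of every feature, fits a random-forest ranker,
counts per-iteration wins against the best shadow and confirms features by
a one-sided binomial sign test at α = 0.05; the union of confirmed sets
over 9 repeats is returned.

## Augmentation and validation

* NCR: known cases get probability 1; candidates are non-known
  participants with mean probability ≥ 0.7, ranked descending (ties by
  participant id). NCR(rank r) = 1 + r / n_known, clipped to [1, 10].
  The four level cut points are the empirical quartiles (linear
  interpolation) of the clipped per-candidate NCR values — "divided into
  four quantiles" is ambiguous about its base distribution, and the
  achievable candidate distribution was chosen because it reproduces the
  worked arithmetic and adapts to shallow candidate pools. Level Lk
  admits ranks ≤ (q_{k+1} − 1) · n_known; new cases are down-sampled,
  highest probability first, to the known-case sex split (within one
  participant), which preserves L0 ⊆ L1 ⊆ L2 ⊆ L3.
* Capped validation: the model trains only on cases diagnosed strictly
  before the cutoff date; every participant outside the training case set
  is scored and the 2 × 2 of (first qualifying diagnosis on/after cutoff)
  × (probability ≥ threshold) is tested with a one-sided Fisher exact
  test. Scoring only non-training participants makes the no-leakage
  contract explicit.

## Association testing and triage

Collapsing tests are two-sided Fisher exact tests on carrier 2 × 2
tables; the odds ratio is the cross-product ratio, with Haldane +0.5 on
all cells (flagged) only when a cell is zero; direction is the sign of
the log OR. Controls per cohort level are the chapter-excluded pool minus
that level's cases, down-sampled to the level's case sex split. The 16
clonal-hematopoiesis genes ship as a default exclusion list. Pan-ancestry
combination uses the Cochran–Mantel–Haenszel 1-df chi-square without
continuity correction and the Mantel–Haenszel pooled OR (statsmodels);
strata with an empty margin are dropped. The quantitative PheWAS is an
OLS of the biomarker on carrier status with sex and age covariates — a
deliberately minimal covariate set, since the original analysis relied on
an external results portal. Triage per (gene, ICD10): known-binary when
the baseline test is also < 1 × 10⁻⁸ with the same direction; otherwise
known-quant when any dominating biomarker (FIZ > 1.2) has quantitative
p < 1 × 10⁻⁸ for the gene; otherwise putative-novel. Thresholds are fixed
(1 × 10⁻⁸ genome-wide, 0.05 nominal); no FDR layer is added.

## Enrichment utilities

Stepwise hypergeometric enrichment tests each prefix of a ranked gene
list against a known set with the one-sided hypergeometric tail; the
curve is max(−10·log₁₀ 0.05, −10·log₁₀ p) and the summary AUC is the mean
curve height above the 0.05 floor (normalized by list length — the
normalization is a package choice). Comorbidity scores are capped,
floored log odds ratios normalized to [0, 100] with cap log 100 by
default ("a high value"). Signature uniqueness counts phenotypes whose
top-N FIS feature sets (ties by feature name) coincide exactly.

## Synthetic biobank

The generator emulates a UK-Biobank-like resource: ~54% female, ages
centred near 57 within 40–69, collection dates 2006–2010, blockwise
per-assay-panel missingness plus per-feature MCAR. Per disease, liability
is Bernoulli with logit α_sex + z + Σ log(m_g)·carrier_g for a latent
severity z ~ N(0,1); sex-specific intercepts are calibrated by bisection
to hit the configured prevalence and case sex bias. Liability-positive
participants receive a latent diagnosis date offset from collection by a
normal lag, and their affected biomarkers shift by the pre- or
post-diagnosis amount according to the lag sign; a cryptic fraction keeps
the shifts but loses the diagnosis record. The bundled default feature
set mirrors a 67-trait clinical battery (30 blood biochemistry, 20 blood
count, 4 urine, 3 spirometry, 4 body size, 3 blood pressure measures,
plus sex/age/fasting-time covariates).

What the generator does **not** emulate: linkage disequilibrium or
variant-level genotypes (carriers are Bernoulli draws), longitudinal
repeat measures, non-normal biomarker distributions, correlated
biomarkers beyond shared disease shifts, and informative (non-random)
missingness. Passing tests therefore demonstrate the pipeline's internal
correctness and its qualitative behaviour under the planted mechanism,
not performance on real biobank data.

Note the latent severity factor attenuates the *marginal* case/control
carrier odds ratio below the planted *conditional* multiplier m (averaging
a logistic over z shrinks covariate effects); the carrier-enrichment test
accounts for this by comparing against the empirical sampling interval.

## Experiment sizes and parameter choices

Synthetic experiments are sized for a single CPU while keeping the
statistical contrasts unambiguous:

* Ensemble recovery: 20,000 participants, ~500 cases, 2-SD shifts on 3 of
  10 biomarkers, 3 seeds (median AUC ≥ 0.9); null calibration at 2,000
  participants over 5 seeds.
* Cryptic-case core claim: 20,000 participants, prevalence 0.04, 30%
  cryptic, 2-SD shifts on 3 of 8 biomarkers, carrier frequency 0.05,
  conditional liability odds multiplier 3.0, diagnosis lags N(0, 8 y)
  with the prognostic 10-year cohort. The multiplier was fixed by a power
  analysis targeting a baseline association z-score near 4 (clearly
  non-significant at 1 × 10⁻⁸) and an augmented z-score near 7 (clearly
  significant), so that the augmentation contrast — not sampling luck —
  decides the outcome.
* `ctrl_ratio_max` = 9 (the method's fallback value) in synthetic
  experiments, because a 19× matched pool is supply-constrained per
  (age bin × sex) cell at desk scale; the library default remains 19.
* Capped validation: 6,000 participants, prevalence 0.08, positive
  diagnosis lags (N(2000 d, 800 d)), cutoff 2014-01-01, 3 seeds; the
  null calibration simulates 200 independent 2 × 2 tables.

## Numerical choices and degenerate inputs

Fisher p-values come from scipy's exact implementation and are verified
against exhaustive hypergeometric enumeration on all tables with total
margin ≤ 30. Zero-carrier tables return p = 1 with direction undefined.
All-zero FIS yields an empty FIZ table; fewer than two nonzero FIS values
yield NaN z-scores. Constant biomarkers in the quantitative test return
(0, 1). Empty candidate pools collapse every augmentation level to the
known cases. Ineligible phenotypes (< 100 cases) are reported as skipped,
not errors.

## Known limitations

Tuning on the training set (by design fidelity) overestimates apparent
performance for large grids; the cross-validated metrics reported by the
Results object are the honest figures. The quantitative-PheWAS covariate
set is minimal. Multi-instance measurement collapsing ("first non-null")
is delegated to the data producer; the generator emits single-instance
tables. The CLI covers the common paths; programmatic use is the primary
interface for compositions beyond them.
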