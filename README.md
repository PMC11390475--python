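# caseforge

Biomarker-driven augmentation of case–control cohorts for rare-variant
collapsing PheWAS, with a synthetic-biobank generator for end-to-end
validation against planted ground truth.

## The problem

Biobank phenotypes are defined from billing codes and self-report, so the
"control" pool of any case–control analysis contains *cryptic cases* —
participants who biologically belong to the case group but are miscoded or
not yet diagnosed. Cryptic cases dilute gene–disease association signals.
caseforge addresses this by learning a disease-specific biomarker
signature from the diagnosed cases, scoring every participant's
probability of being a case, promoting high-probability controls into
augmented case cohorts, and re-running gene-level collapsing association
tests on the augmented cohorts.

## The method

For each disease code (ICD10) with ≥ 100 known cases:

1. **Cohorts.** Cases are everyone diagnosed with the code or any
   sub-node, optionally restricted by a *time-model* relating diagnosis to
   biomarker sampling: prognostic (diagnosed 0–*t* years after sample
   collection), diagnostic (0–*t* years before) or time-agnostic, with
   *t* = 10 by default. Sex-specific phenotypes (dominant-sex proportion
   > 0.9) drop minority-sex cases. Controls exclude anyone diagnosed in
   the code's ICD10 chapter and are matched to the case distribution over
   four age bins × sex at an integer controls-per-case ratio
   (`ctrl_ratio` ≤ 19, or 9 when supply is short).
2. **Balanced ensemble.** Features are median-imputed (with clinical
   detection-limit rules for rheumatoid factor, oestradiol and
   testosterone), one-hot encoded and standardized on training data only.
   An XGBoost tree count is tuned over {50, 100, 200, 300} on one balanced
   set; then, in each of 10 replicates × 5 CV folds, the training controls
   are partitioned into `ctrl_ratio` subsamples and one classifier is
   trained per balanced case/control subsample (e.g. 19 × 5 × 10 = 950
   submodels). Per-replicate full-data models score the whole population;
   the mean probability P(case) per participant is the output.
3. **Augmentation (NCR).** Known cases get probability 1; other
   participants with P ≥ 0.7 are ranked by descending probability. Rank
   *r* maps to a novel case ratio NCR = 1 + *r*/n_known, clipped to
   [1, 10]; its quartiles define four nested cohorts L0 ⊆ L1 ⊆ L2 ⊆ L3,
   each sex-matched to the known cases.
4. **Collapsing PheWAS.** Per gene and qualifying-variant (QV) model, a
   two-sided Fisher exact test on the 2 × 2 carrier table at every cohort
   level; p < 1 × 10⁻⁸ is genome-wide significant. Clonal-hematopoiesis
   genes (DNMT3A, TET2, …) are excluded. Per-ancestry tables can be
   combined with a Cochran–Mantel–Haenszel test. Hits are triaged into
   **known-binary** (baseline-significant, same direction), **known-quant**
   (a dominating biomarker — feature-importance z-score FIZ > 1.2 — is
   itself gene-significant in a quantitative PheWAS) and
   **putative-novel**.
5. **Diagnostics.** Feature importance scores (mean normalized gain, FIS),
   their z-scores after log transform (FIZ), temporal ("capped")
   validation — train before a cutoff date, test enrichment of high
   probabilities among post-cutoff diagnoses — stepwise hypergeometric
   enrichment against external gene rankings, comorbidity scoring and
   top-N signature uniqueness.

Because real biobank data cannot ship with the package, the
`caseforge.simulate` module generates a biobank with planted truth:
logistic liability per disease, biomarker shifts that differ before vs
after diagnosis, carriers with known liability odds multipliers, blockwise
assay missingness and a configurable fraction of cryptic cases.

## Worked example

```python
from caseforge import (DiseaseSpec, FeatureSpec, GeneSpec, RunConfig,
                       SimConfig, generate_biobank, run_single_phenotype)

feats = tuple(FeatureSpec(name=f"bm{i}", mean=10, sd=2) for i in range(6))
disease = DiseaseSpec(icd10="N18", prevalence=0.05,
                      affected_features={"bm0": (2.0, 2.0), "bm1": (1.5, 1.5)},
                      cryptic_fraction=0.2)
gene = GeneSpec(gene="PKD1", carrier_freq=0.05, odds_multiplier={"N18": 3.0})
biobank, truth = generate_biobank(SimConfig(
    n_participants=10_000, seed=42, features=feats,
    diseases=(disease,), genes=(gene,)))
run = run_single_phenotype(
    biobank, "N18", RunConfig(phenotypes=("N18",), ctrl_ratio_max=9, seed=42))
print(run.results.summary())
```

```
Disease signature ensemble: N18
============================================
n_estimators (tuned)   50
submodels              450
replicates             10
median AUC             0.942
median sensitivity     0.890
median specificity     0.867

Top features by FIS (z after log transform; * dominating > 1.2):
  * bm0                                  FIS 0.4960  z   2.17
    bm1                                  FIS 0.2135  z   1.18
    bm3                                  FIS 0.0526  z  -0.46
    ...
```

The ensemble recovers the planted signature: `bm0` (the 2-SD-shifted
biomarker) dominates with FIS 0.50 and FIZ 2.17 > 1.2; the cross-validated
median AUC is 0.94. The augmented cohorts grow from 427 (L0) to 494 (L3)
cases around the 409 known cases, and the collapsing test for the planted
gene stays genome-wide significant at every level
(`run.associations`: PKD1 baseline OR 2.96, p 8.4 × 10⁻¹⁰). Of the 118
cryptic cases hidden by the generator, 27 are recovered inside L3 — a far
higher rate than for true controls, which is exactly the enrichment that
powers augmented discovery on larger biobanks.

A command-line interface mirrors the library:

```bash
caseforge simulate sim.yaml --out bundle/
caseforge cohort bundle/ --icd10 N18 --time-model prognostic --lag 10
caseforge train bundle/ --icd10 N18 --out artifacts/
caseforge phewas bundle/ --cohorts artifacts/N18/augmented_cohorts.json --out assoc.tsv
```

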