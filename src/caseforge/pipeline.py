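"""Per-phenotype and phenome-wide orchestration of the full pipeline.

One phenotype runs: case collection under a time-model -> sex filter ->
matched control selection -> preprocessing fitted on the cohort ->
balanced-ensemble training -> population prediction -> NCR augmentation ->
collapsing PheWAS on baseline and L0-L3 cohorts -> hit triage ->
comorbidity enrichment. Every artefact is written to a per-phenotype
directory together with a run log carrying the seeds and the config hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .augment import build_ncr_cohorts, rank_candidates
from .biobank import Biobank
from .cohorts import (
    TimeModelSpec,
    apply_sex_filter,
    apply_time_model,
    collect_cases,
    potential_controls,
    select_controls,
)
from .enrich import comorbidity_enrichment
from .ensemble import DiseaseSignatureModel, EnsembleConfig
from .phewas import classify_hits, min_p_summary, run_phewas
from .preprocess import Preprocessor
from .specs import ConfigError, FeatureSpec

__all__ = ["RunConfig", "PhenotypeRun", "run_single_phenotype", "run_phenome"]


@dataclass(frozen=True)
class RunConfig:
    """Pipeline-wide thresholds and knobs; defaults follow the method."""

    phenotypes: tuple[str, ...] = ()
    time_model: TimeModelSpec = TimeModelSpec("time-agnostic", 10)
    ensemble: EnsembleConfig = EnsembleConfig()
    case_probability_threshold: float = 0.7
    significance_threshold: float = 1e-8
    fiz_threshold: float = 1.2
    sex_filter_threshold: float = 0.9
    ctrl_ratio_max: int = 19
    seed: int = 0
    feature_specs: tuple[FeatureSpec, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.case_probability_threshold <= 1.0:
            raise ConfigError("case probability threshold must be in (0, 1]")
        if not 0.0 < self.significance_threshold < 1.0:
            raise ConfigError("significance threshold must be in (0, 1)")

    def digest(self) -> str:
        payload = json.dumps({
            "phenotypes": list(self.phenotypes),
            "time_model": [self.time_model.kind, self.time_model.lag_years],
            "ensemble": [list(self.ensemble.n_estimators_grid),
                         self.ensemble.n_folds, self.ensemble.n_replicates],
            "thresholds": [self.case_probability_threshold,
                           self.significance_threshold, self.fiz_threshold,
                           self.sex_filter_threshold],
            "ctrl_ratio_max": self.ctrl_ratio_max,
            "seed": self.seed,
        }, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PhenotypeRun:
    """Artefacts of one per-phenotype run (``skipped`` when ineligible)."""

    icd10: str
    skipped: bool = False
    reason: str = ""
    cohort: object = None
    results: object = None
    augmented: object = None
    associations: pd.DataFrame = field(default_factory=pd.DataFrame)
    triage: pd.DataFrame = field(default_factory=pd.DataFrame)
    comorbidity: pd.DataFrame = field(default_factory=pd.DataFrame)


def _feature_table(biobank: Biobank) -> pd.DataFrame:
    return biobank.biomarkers.merge(
        biobank.participants[["eid", "sex", "age"]], on="eid"
    ).set_index("eid")


def _default_specs(biobank: Biobank) -> list[FeatureSpec]:
    """Biomarker columns plus the sex and age covariates."""
    return ([FeatureSpec(name=n) for n in biobank.feature_names()]
            + [FeatureSpec(name="sex", role="categorical"),
               FeatureSpec(name="age", role="covariate")])


def run_single_phenotype(
    biobank: Biobank,
    icd10: str,
    config: RunConfig = RunConfig(),
    outdir: str | Path | None = None,
) -> PhenotypeRun:
    """Run the full pipeline for one ICD10 code.

    Ineligible phenotypes (fewer than 100 known cases after filtering)
    are returned as skipped rather than raising.
    """
    log: list[str] = [f"phenotype={icd10} seed={config.seed} "
                      f"config_hash={config.digest()}"]
    case_set = collect_cases(
        biobank.diagnoses, biobank.hierarchy, biobank.participants, icd10
    )
    case_set = apply_time_model(case_set, config.time_model)
    case_set = apply_sex_filter(case_set, biobank.participants,
                                config.sex_filter_threshold)
    log.append(f"cases={case_set.n_cases} time_model={config.time_model.kind} "
               f"sex_filtered={case_set.sex_filtered}")
    if not case_set.eligible:
        run = PhenotypeRun(icd10, skipped=True,
                           reason=f"{case_set.n_cases} cases < 100 required")
        log.append(f"skipped: {run.reason}")
        _write_artifacts(run, config, log, outdir)
        return run

    cohort = select_controls(
        case_set, biobank.participants, biobank.diagnoses, biobank.hierarchy,
        ctrl_ratio_max=config.ctrl_ratio_max, seed=config.seed,
    )
    log.append(f"controls={len(cohort.control_ids)} ctrl_ratio={cohort.ctrl_ratio}")

    specs = (list(config.feature_specs) if config.feature_specs is not None
             else _default_specs(biobank))
    table = _feature_table(biobank)
    prep = Preprocessor(specs)
    train_ids = np.concatenate([cohort.case_ids, cohort.control_ids])
    prep.fit(table.loc[train_ids])
    mat, cols = prep.transform(table)
    features = pd.DataFrame(mat, index=table.index, columns=cols)

    ens_config = EnsembleConfig(
        n_estimators_grid=config.ensemble.n_estimators_grid,
        n_folds=config.ensemble.n_folds,
        n_replicates=config.ensemble.n_replicates,
        prob_threshold=config.ensemble.prob_threshold,
        base_seed=config.seed,
        tune_cv=config.ensemble.tune_cv,
    )
    results = DiseaseSignatureModel(features, cohort, ens_config).fit()
    log.append(f"n_estimators={results.n_estimators} "
               f"median_auc={results.median_auc:.3f}")

    ranked = rank_candidates(results.predictions, cohort.case_ids,
                             config.case_probability_threshold)
    augmented = build_ncr_cohorts(ranked, cohort.case_ids,
                                  biobank.participants, icd10)
    log.append("levels=" + " ".join(
        f"{lvl}:{len(ids)}" for lvl, ids in augmented.levels.items()))

    associations = pd.DataFrame()
    triage = pd.DataFrame()
    if len(biobank.carriers):
        pool = potential_controls(biobank.participants, biobank.diagnoses,
                                  biobank.hierarchy, icd10)
        levels = {"baseline": cohort.case_ids} | augmented.levels
        associations = run_phewas(
            levels, pool, biobank.carriers, biobank.participants,
            icd10=icd10, seed=config.seed,
        )
        milton = min_p_summary(
            associations.loc[associations["level"] != "baseline"])
        baseline = associations.loc[associations["level"] == "baseline"]
        baseline = min_p_summary(baseline) if len(baseline) else baseline
        quant = pd.DataFrame(columns=["gene", "feature", "p_value"])
        triage = classify_hits(
            milton, baseline, quant, {icd10: results.fiz_table},
            sig_threshold=config.significance_threshold,
            fiz_threshold=config.fiz_threshold,
        ) if len(milton) else pd.DataFrame()
        log.append(f"associations={len(associations)} hits={len(triage)}")

    comorbidity = comorbidity_enrichment(
        augmented.levels["L3"], biobank.diagnoses,
        biobank.participants["eid"],
    )

    run = PhenotypeRun(icd10, cohort=cohort, results=results,
                       augmented=augmented, associations=associations,
                       triage=triage, comorbidity=comorbidity)
    _write_artifacts(run, config, log, outdir)
    return run


def _write_artifacts(run: PhenotypeRun, config: RunConfig,
                     log: list[str], outdir) -> None:
    if outdir is None:
        return
    outdir = Path(outdir) / run.icd10
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = f"# config_hash={config.digest()}\n"
    (outdir / "run.log").write_text("\n".join(log) + "\n")
    if run.skipped:
        (outdir / "skipped.json").write_text(json.dumps(
            {"icd10": run.icd10, "reason": run.reason,
             "config_hash": config.digest()}, indent=1))
        return
    res = run.results
    (outdir / "model_summary.json").write_text(json.dumps({
        "icd10": run.icd10,
        "config_hash": config.digest(),
        "n_estimators": res.n_estimators,
        "n_submodels": res.n_submodels,
        "ctrl_ratio": run.cohort.ctrl_ratio,
        "replicate_metrics": res.replicate_metrics.to_dict(orient="records"),
        "median_auc": res.median_auc,
    }, indent=1))
    with open(outdir / "predictions.tsv", "w") as fh:
        fh.write(stamp)
        res.predictions.rename_axis("eid").to_csv(fh, sep="\t")
    fis_out = res.fiz_table.copy()
    fis_out.insert(0, "feature", fis_out.index)
    with open(outdir / "fis.tsv", "w") as fh:
        fh.write(stamp)
        fis_out.to_csv(fh, sep="\t", index=False)
    (outdir / "augmented_cohorts.json").write_text(json.dumps({
        "icd10": run.icd10,
        "config_hash": config.digest(),
        "n_known": run.augmented.n_known,
        "cut_points": run.augmented.cut_points,
        "levels": {lvl: [int(e) for e in ids]
                   for lvl, ids in run.augmented.levels.items()},
    }, indent=1))
    for name, df in (("associations.tsv", run.associations),
                     ("triage.tsv", run.triage),
                     ("comorbidity.tsv", run.comorbidity)):
        if len(df):
            with open(outdir / name, "w") as fh:
                fh.write(stamp)
                df.to_csv(fh, sep="\t", index=False)


def run_phenome(
    biobank: Biobank,
    config: RunConfig,
    outdir: str | Path | None = None,
) -> pd.DataFrame:
    """Run every configured phenotype; return the triage-count rollup.

    One summary row per phenotype with case counts, median AUC and the
    known-binary / known-quant / putative-novel hit counts; skipped
    phenotypes are reported with their reason.
    """
    if not config.phenotypes:
        import warnings

        warnings.warn("empty phenotype list; nothing to run", stacklevel=2)
        return pd.DataFrame()
    rows = []
    for icd10 in config.phenotypes:
        run = run_single_phenotype(biobank, icd10, config, outdir)
        counts = (run.triage["label"].value_counts().to_dict()
                  if len(run.triage) else {})
        rows.append({
            "icd10": icd10,
            "skipped": run.skipped,
            "reason": run.reason,
            "n_cases": 0 if run.skipped else len(run.cohort.case_ids),
            "median_auc": np.nan if run.skipped else run.results.median_auc,
            "known_binary": counts.get("known-binary", 0),
            "known_quant": counts.get("known-quant", 0),
            "putative_novel": counts.get("putative-novel", 0),
        })
    summary = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        summary.to_csv(outdir / "phenome_summary.tsv", sep="\t", index=False)
    return summary
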