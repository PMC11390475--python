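"""Balanced ensemble of gradient-boosted tree classifiers.

Class imbalance is handled by a balanced ensemble: within every
cross-validation fold the training controls are partitioned into
``ctrl_ratio`` disjoint subsamples of case-set size, one XGBoost classifier
is trained per subsample on a balanced case/control set, and fold
performance is the mean over those submodels. The whole procedure is
replicated ``n_replicates`` times with fresh fold splits and control
partitions, so with ctrl_ratio 19, 5 folds and 10 replicates the ensemble
comprises 19 x 5 x 10 = 950 submodels and every control is used exactly
once per (replicate, fold).

Population-wide case probabilities come from one full-data classifier per
replicate, averaged across replicates. Feature importance scores (FIS) are
gain importances normalized to sum 1 per submodel and averaged over all
submodels; their z-scores after log transform (FIZ) flag "dominating"
features above 1.2.

The public surface follows the Model/Results convention:
``DiseaseSignatureModel(features, cohort, config).fit()`` returns a
:class:`DiseaseSignatureResults` carrying metrics, importances and
predictions, with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from ._seeds import child_seed
from .cohorts import Cohort

__all__ = [
    "EnsembleConfig",
    "DiseaseSignatureModel",
    "DiseaseSignatureResults",
    "tune_n_estimators",
    "compute_fiz",
]

DEFAULT_GRID = (50, 100, 200, 300)


@dataclass(frozen=True)
class EnsembleConfig:
    n_estimators_grid: tuple[int, ...] = DEFAULT_GRID
    n_folds: int = 5
    n_replicates: int = 10
    prob_threshold: float = 0.5
    base_seed: int = 0
    tune_cv: bool = False

    def __post_init__(self) -> None:
        if not self.n_estimators_grid:
            raise ValueError("n_estimators grid must be non-empty")
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")
        if self.n_replicates < 1:
            raise ValueError("need at least 1 replicate")


def _make_xgb(n_estimators: int, seed: int) -> XGBClassifier:
    return XGBClassifier(
        n_estimators=n_estimators,
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        eval_metric="logloss",
        verbosity=0,
    )


def _gain_importance(clf: XGBClassifier, feature_names: list[str]) -> np.ndarray:
    score = clf.get_booster().get_score(importance_type="gain")
    arr = np.array([score.get(name, 0.0) for name in feature_names], float)
    total = arr.sum()
    return arr / total if total > 0 else arr


def tune_n_estimators(
    X: pd.DataFrame,
    y: np.ndarray,
    grid: tuple[int, ...] = DEFAULT_GRID,
    seed: int = 0,
    cv: bool = False,
) -> int:
    """Pick the tree count with the highest AUROC on a balanced set.

    By default the candidate models are scored on the very data they were
    fitted on (apparent AUROC); ``cv=True`` scores them by 3-fold
    cross-validation instead. Ties go to the smallest candidate.
    """
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("tuning set must contain both classes")
    best_val, best_n = -np.inf, None
    for n in sorted(grid):
        if cv:
            aucs = []
            skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
            for tr, te in skf.split(X, y):
                clf = _make_xgb(n, seed).fit(X.iloc[tr], y[tr])
                aucs.append(roc_auc_score(y[te], clf.predict_proba(X.iloc[te])[:, 1]))
            val = float(np.mean(aucs))
        else:
            clf = _make_xgb(n, seed).fit(X, y)
            val = float(roc_auc_score(y, clf.predict_proba(X)[:, 1]))
        if val > best_val:
            best_val, best_n = val, n
    return int(best_n)


def compute_fiz(fis: pd.Series, threshold: float = 1.2) -> pd.DataFrame:
    """Z-score the log of the nonzero feature importance scores.

    Zero-FIS features are excluded from the transform (their log is
    undefined) and reported with NaN z-scores. The z-score uses the
    population SD, and is invariant to the logarithm base. Features with
    z above ``threshold`` are flagged as dominating.
    """
    fis = fis.astype(float)
    nz = fis[fis > 0]
    out = pd.DataFrame({"fis": fis, "fiz": np.nan, "dominating": False})
    if nz.size < 2:
        return out
    logs = np.log(nz.to_numpy())
    sd = logs.std(ddof=0)
    z = np.zeros_like(logs) if sd == 0 else (logs - logs.mean()) / sd
    out.loc[nz.index, "fiz"] = z
    out.loc[nz.index, "dominating"] = z > threshold
    return out


@dataclass
class DiseaseSignatureResults:
    """Fit artefacts of a balanced disease-signature ensemble."""

    icd10: str
    config: EnsembleConfig
    n_estimators: int
    replicate_metrics: pd.DataFrame  # replicate, auc, sensitivity, specificity
    fis: pd.Series
    fiz_table: pd.DataFrame
    n_submodels: int
    feature_names: list[str]
    _replicate_models: list = field(default_factory=list, repr=False)
    predictions: pd.Series | None = None

    # ------------------------------------------------------------- metrics
    @property
    def median_auc(self) -> float:
        return float(self.replicate_metrics["auc"].median())

    @property
    def median_sensitivity(self) -> float:
        return float(self.replicate_metrics["sensitivity"].median())

    @property
    def median_specificity(self) -> float:
        return float(self.replicate_metrics["specificity"].median())

    def performance_summary(self) -> dict:
        return {
            "median_auc": self.median_auc,
            "median_sensitivity": self.median_sensitivity,
            "median_specificity": self.median_specificity,
        }

    @property
    def dominating_features(self) -> list[str]:
        t = self.fiz_table
        return list(t.index[t["dominating"]])

    # ---------------------------------------------------------- prediction
    def predict(self, features: pd.DataFrame) -> pd.Series:
        """Mean case probability across the per-replicate full-data models.

        ``features`` must be indexed by participant id with the model's
        feature columns.
        """
        if list(features.columns) != self.feature_names:
            raise ValueError("feature columns do not match the fitted model")
        probs = np.zeros(len(features))
        for clf in self._replicate_models:
            probs += clf.predict_proba(features)[:, 1]
        probs /= len(self._replicate_models)
        return pd.Series(probs, index=features.index, name="p_case")

    def summary(self) -> str:
        m = self.replicate_metrics
        lines = [
            f"Disease signature ensemble: {self.icd10}",
            "=" * 44,
            f"n_estimators (tuned)   {self.n_estimators}",
            f"submodels              {self.n_submodels}",
            f"replicates             {len(m)}",
            f"median AUC             {self.median_auc:.3f}",
            f"median sensitivity     {self.median_sensitivity:.3f}",
            f"median specificity     {self.median_specificity:.3f}",
            "",
            "Top features by FIS (z after log transform; * dominating > 1.2):",
        ]
        top = self.fis.sort_values(ascending=False).head(10)
        for name in top.index:
            z = self.fiz_table.loc[name, "fiz"]
            star = "*" if bool(self.fiz_table.loc[name, "dominating"]) else " "
            ztxt = f"{z:6.2f}" if np.isfinite(z) else "   na "
            lines.append(f"  {star} {name:<36s} FIS {self.fis[name]:.4f}  z {ztxt}")
        return "\n".join(lines)


class DiseaseSignatureModel:
    """Balanced XGBoost ensemble for one phenotype.

    Parameters
    ----------
    features : pd.DataFrame
        Preprocessed numeric feature matrix indexed by participant id.
        Must cover every cohort participant; any additional rows are scored
        at prediction time.
    cohort : Cohort
        Matched case/control cohort; ``cohort.ctrl_ratio`` controls the
        number of balanced subsamples per fold.
    config : EnsembleConfig
    """

    def __init__(self, features: pd.DataFrame, cohort: Cohort,
                 config: EnsembleConfig = EnsembleConfig()):
        missing = [e for e in np.concatenate([cohort.case_ids, cohort.control_ids])
                   if e not in features.index]
        if missing:
            raise ValueError(f"feature matrix missing cohort ids, e.g. {missing[:3]}")
        if cohort.ctrl_ratio < 1:
            raise ValueError("cohort ctrl_ratio must be >= 1")
        if len(cohort.case_ids) < config.n_folds:
            raise ValueError("fewer cases than folds")
        self.features = features
        self.cohort = cohort
        self.config = config

    # ------------------------------------------------------------------ fit
    def fit(self, predict_population: bool = True) -> DiseaseSignatureResults:
        cfg = self.config
        cohort = self.cohort
        ratio = cohort.ctrl_ratio
        cases = np.sort(cohort.case_ids)
        controls = np.sort(cohort.control_ids)
        n_cases = cases.size

        # hyperparameter tuning on one balanced set
        rng = np.random.default_rng(child_seed(cfg.base_seed, "tune", cohort.icd10))
        tune_controls = rng.permutation(controls)[:n_cases]
        tune_ids = np.concatenate([cases, tune_controls])
        X_tune = self.features.loc[tune_ids]
        y_tune = np.r_[np.ones(n_cases), np.zeros(tune_controls.size)]
        n_estimators = tune_n_estimators(
            X_tune, y_tune, cfg.n_estimators_grid,
            seed=child_seed(cfg.base_seed, "tune-fit", cohort.icd10),
            cv=cfg.tune_cv,
        )

        rep_rows = []
        fis_acc = np.zeros(self.features.shape[1])
        n_submodels = 0
        replicate_models = []
        feature_names = list(self.features.columns)

        for r in range(cfg.n_replicates):
            rrng = np.random.default_rng(child_seed(cfg.base_seed, "replicate", r))
            rep_controls = rrng.permutation(controls)[: ratio * n_cases]
            ids = np.concatenate([cases, rep_controls])
            y = np.r_[np.ones(n_cases), np.zeros(rep_controls.size)]
            X = self.features.loc[ids]

            skf = StratifiedKFold(
                n_splits=cfg.n_folds, shuffle=True,
                random_state=child_seed(cfg.base_seed, "folds", r),
            )
            fold_metrics = []
            for f, (tr, te) in enumerate(skf.split(X, y)):
                tr_cases = tr[y[tr] == 1]
                tr_controls = rrng.permutation(tr[y[tr] == 0])
                chunks = np.array_split(tr_controls, ratio)
                sub_metrics = []
                for s, chunk in enumerate(chunks):
                    idx = np.concatenate([tr_cases, chunk])
                    clf = _make_xgb(
                        n_estimators,
                        child_seed(cfg.base_seed, "sub", r, f, s),
                    ).fit(X.iloc[idx], y[idx])
                    p = clf.predict_proba(X.iloc[te])[:, 1]
                    yt = y[te]
                    pred = p >= cfg.prob_threshold
                    sens = float(pred[yt == 1].mean()) if (yt == 1).any() else np.nan
                    spec = float((~pred[yt == 0]).mean()) if (yt == 0).any() else np.nan
                    auc = (roc_auc_score(yt, p)
                           if np.unique(yt).size == 2 else np.nan)
                    sub_metrics.append((auc, sens, spec))
                    fis_acc += _gain_importance(clf, feature_names)
                    n_submodels += 1
                fold_metrics.append(np.nanmean(np.array(sub_metrics), axis=0))
            rep_auc, rep_sens, rep_spec = np.nanmean(np.array(fold_metrics), axis=0)
            rep_rows.append((r, rep_auc, rep_sens, rep_spec))

            full = _make_xgb(
                n_estimators, child_seed(cfg.base_seed, "full", r)
            ).fit(X, y)
            replicate_models.append(full)

        fis = pd.Series(fis_acc / n_submodels, index=feature_names, name="fis")
        results = DiseaseSignatureResults(
            icd10=cohort.icd10,
            config=cfg,
            n_estimators=n_estimators,
            replicate_metrics=pd.DataFrame(
                rep_rows, columns=["replicate", "auc", "sensitivity", "specificity"]
            ),
            fis=fis,
            fiz_table=compute_fiz(fis),
            n_submodels=n_submodels,
            feature_names=feature_names,
            _replicate_models=replicate_models,
        )
        if predict_population:
            results.predictions = results.predict(self.features)
        return results
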