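"""Feature pre-processing fitted on training rows only.

The pipeline is imputation -> one-hot encoding -> standardization, with all
statistics (medians, category vocabularies, means, SDs) estimated from the
training table and then applied unchanged to any other table, so test rows
can never leak into the fitted statistics.

Imputation rules follow clinical-assay conventions: most quantitative
features are imputed with their training median; rheumatoid factor with a
constant 0 IU/ml and oestradiol with sex-specific reference constants
(36.71 pmol/l for men, 110.13 pmol/l for women) because missingness in
those assays reflects values below the detection limit rather than a
skipped test; testosterone uses sex-specific training medians.
"""

from __future__ import annotations

from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from ._seeds import child_seed
from .specs import FeatureSpec

__all__ = ["Preprocessor", "select_features_shadow", "load_default_features"]


class Preprocessor:
    """Imputer + one-hot encoder + standardizer, fitted on training data.

    Scaling uses the population standard deviation (``ddof=0``); features
    constant on the training data map to all-zero columns rather than
    dividing by zero, and categories unseen in training encode to an
    all-zero block.
    """

    def __init__(self, feature_specs: Sequence[FeatureSpec]):
        names = [f.name for f in feature_specs]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        self.feature_specs = list(feature_specs)
        self._fitted = False

    # ------------------------------------------------------------------ fit
    def fit(self, train: pd.DataFrame) -> "Preprocessor":
        if len(train) == 0:
            raise ValueError("training table is empty")
        self.impute_values_: dict[str, object] = {}
        self.vocabularies_: dict[str, list] = {}
        for spec in self.feature_specs:
            col = self._column(train, spec.name)
            if spec.role == "categorical":
                vocab = sorted(col.dropna().unique().tolist())
                self.vocabularies_[spec.name] = vocab
                continue
            self.impute_values_[spec.name] = self._fit_imputation(train, spec, col)

        filled = self._impute_and_encode(train)
        self.columns_ = list(filled.columns)
        mat = filled.to_numpy(float)
        self.means_ = mat.mean(axis=0)
        self.sds_ = mat.std(axis=0, ddof=0)
        self._fitted = True
        return self

    def _fit_imputation(self, train, spec, col):
        rule = spec.special_imputation or {}
        kind = rule.get("kind", "median")
        if kind == "constant":
            return float(rule["value"])
        if kind == "sex_constant":
            return {"M": float(rule["male"]), "F": float(rule["female"])}
        if kind == "sex_median":
            sex = train["sex"].astype(str)
            out = {}
            for s in ("M", "F"):
                vals = col[(sex == s).to_numpy()].dropna()
                if vals.empty:
                    raise ValueError(
                        f"feature {spec.name!r}: no non-missing training values "
                        f"for sex {s!r}"
                    )
                out[s] = float(vals.median())
            return out
        if kind == "median":
            vals = col.dropna()
            if vals.empty:
                raise ValueError(
                    f"feature {spec.name!r} is entirely missing in training data "
                    "and has no special imputation rule"
                )
            return float(vals.median())
        raise ValueError(f"unknown imputation kind {kind!r} for {spec.name!r}")

    # ------------------------------------------------------------ transform
    def transform(self, table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        """Return the standardized numeric matrix and its column names."""
        if not self._fitted:
            raise RuntimeError("Preprocessor.transform called before fit")
        filled = self._impute_and_encode(table)
        mat = filled.to_numpy(float)
        safe_sd = np.where(self.sds_ > 0, self.sds_, 1.0)
        out = (mat - self.means_) / safe_sd
        out[:, self.sds_ == 0] = 0.0
        return out, list(self.columns_)

    def fit_transform(self, train: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        return self.fit(train).transform(train)

    # -------------------------------------------------------------- helpers
    def _column(self, table: pd.DataFrame, name: str) -> pd.Series:
        if name not in table.columns:
            raise KeyError(f"feature column {name!r} missing from table")
        return table[name]

    def _impute_and_encode(self, table: pd.DataFrame) -> pd.DataFrame:
        blocks: dict[str, np.ndarray] = {}
        for spec in self.feature_specs:
            col = self._column(table, spec.name)
            if spec.role == "categorical":
                vocab = self.vocabularies_[spec.name]
                for v in vocab:
                    blocks[f"{spec.name}={v}"] = (col == v).to_numpy(float)
                continue
            imp = self.impute_values_[spec.name]
            vals = col.to_numpy(float, na_value=np.nan)
            if isinstance(imp, dict):  # sex-specific value
                sex = table["sex"].astype(str).to_numpy()
                fill = np.where(sex == "F", imp["F"], imp["M"])
            else:
                fill = np.full(len(table), float(imp))
            blocks[spec.name] = np.where(np.isnan(vals), fill, vals)
        return pd.DataFrame(blocks, index=table.index)


def load_default_features() -> list[FeatureSpec]:
    """The bundled 67-trait feature set (blood, urine, physical measures,
    plus sex/age/fasting-time covariates) with its special imputation rules."""
    text = resources.files("caseforge.data").joinpath("ukb67_features.yaml").read_text()
    entries = yaml.safe_load(text)
    return [FeatureSpec(**e) for e in entries]


def select_features_shadow(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    repeats: int = 9,
    seed: int = 0,
    n_iterations: int = 12,
    alpha: float = 0.05,
    n_trees: int = 60,
) -> list:
    """Shadow-feature (Boruta-style) selection for wide feature sets.

    In every internal iteration each feature is paired with a permuted
    "shadow" copy; a random-forest importance ranker is fitted on the
    joint matrix and a feature scores a hit when its importance beats the
    best shadow. A feature is confirmed within one repeat when its hit
    count is significantly above the fair-coin expectation (one-sided
    binomial sign test at ``alpha``). The union of confirmed features over
    ``repeats`` independent repeats is returned, deterministic in ``seed``.
    """
    from scipy.stats import binomtest
    from sklearn.ensemble import RandomForestClassifier

    X = pd.DataFrame(X)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("shadow selection needs at least 2 classes")
    if counts.min() < 10:
        raise ValueError("shadow selection needs >= 10 samples per class")

    names = list(X.columns)
    mat = X.to_numpy(float)
    n, p = mat.shape
    confirmed: set = set()
    for r in range(repeats):
        rng = np.random.default_rng(child_seed(seed, "shadow", r))
        hits = np.zeros(p, dtype=int)
        for it in range(n_iterations):
            shadow = mat.copy()
            for j in range(p):
                rng.shuffle(shadow[:, j])
            joint = np.hstack([mat, shadow])
            clf = RandomForestClassifier(
                n_estimators=n_trees,
                random_state=child_seed(seed, "shadow-rf", r, it),
                n_jobs=1,
            ).fit(joint, y)
            imp = clf.feature_importances_
            hits += imp[:p] > imp[p:].max()
        for j in range(p):
            test = binomtest(int(hits[j]), n_iterations, 0.5, alternative="greater")
            if test.pvalue < alpha:
                confirmed.add(names[j])
    return sorted(confirmed, key=names.index)
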