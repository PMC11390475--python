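"""Novel-case-ratio (NCR) cohort augmentation and temporal validation.

Known cases are assigned probability 1; every other participant with mean
predicted case probability at or above a threshold (default 0.7) becomes a
candidate, ranked by descending probability. Rank ``r`` maps to
``NCR = 1 + r / n_known``; NCR is clipped to [1, 10] and its empirical
quartiles define four nested augmentation levels L0 (conservative) to L3
(inclusive). New cases at each level are down-sampled so their sex split
matches the known cases.

The capped (temporal hold-out) validation trains on cases diagnosed before
a cutoff date only and tests whether post-cutoff diagnoses are enriched
among participants predicted above threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .cohorts import (
    CaseSet,
    TimeModelSpec,
    apply_time_model,
    collect_cases,
    descendant_codes,
    select_controls,
)

__all__ = [
    "RankedCandidates",
    "AugmentedCohorts",
    "CappedValidationResult",
    "rank_candidates",
    "build_ncr_cohorts",
    "capped_validation",
    "capped_table_test",
]

NCR_MAX = 10.0
LEVELS = ("L0", "L1", "L2", "L3")


@dataclass
class RankedCandidates:
    """Candidates above threshold, ranked by descending probability."""

    table: pd.DataFrame  # columns: eid, prob, rank, ncr
    n_known: int
    threshold: float

    def ncr_at_rank(self, rank: int) -> float:
        """NCR reached when candidates up to ``rank`` are included."""
        return 1.0 + rank / self.n_known


@dataclass
class AugmentedCohorts:
    """The four nested augmented case cohorts plus their NCR cut points."""

    icd10: str
    levels: dict[str, np.ndarray]  # level -> case ids (known + new)
    new_cases: dict[str, np.ndarray]  # level -> new case ids only
    cut_points: dict[str, float]  # q1..q4 over the clipped NCR values
    n_known: int


@dataclass
class CappedValidationResult:
    cutoff_date: pd.Timestamp
    threshold: float
    table: np.ndarray  # [[a, b], [c, d]]
    odds_ratio: float
    p_value: float


def rank_candidates(
    predictions: pd.Series,
    known_case_ids,
    threshold: float = 0.7,
) -> RankedCandidates:
    """Rank non-known participants with probability >= ``threshold``.

    Ties in probability are broken by participant id, so ranking is stable
    across runs. Known cases never appear among the candidates.
    """
    known = set(known_case_ids)
    if not known:
        raise ValueError("need at least one known case to define the NCR")
    cand = predictions.drop(index=[e for e in predictions.index if e in known])
    cand = cand[cand >= threshold]
    tab = (
        cand.rename("prob")
        .rename_axis("eid")
        .reset_index()
        .sort_values(["prob", "eid"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    tab["rank"] = np.arange(1, len(tab) + 1)
    tab["ncr"] = 1.0 + tab["rank"] / len(known)
    return RankedCandidates(table=tab, n_known=len(known), threshold=threshold)


def _sex_matched_subset(
    cand: pd.DataFrame, sex_by_eid: pd.Series, female_frac: float
) -> np.ndarray:
    """Largest highest-probability-first subset matching the known-case sex
    split within one participant of rounding."""
    cand_sex = cand["eid"].map(sex_by_eid)
    females = cand.loc[(cand_sex == "F").to_numpy(), "eid"].to_numpy()
    males = cand.loc[(cand_sex == "M").to_numpy(), "eid"].to_numpy()
    if female_frac >= 1.0:
        return females
    if female_frac <= 0.0:
        return males
    total = min(int(np.floor(len(females) / female_frac)),
                int(np.floor(len(males) / (1.0 - female_frac))))
    keep_f = min(int(round(female_frac * total)), len(females))
    keep_m = min(total - keep_f, len(males))
    return np.concatenate([females[:keep_f], males[:keep_m]])


def build_ncr_cohorts(
    ranked: RankedCandidates,
    known_case_ids,
    participants: pd.DataFrame,
    icd10: str = "",
) -> AugmentedCohorts:
    """Cut the clipped candidate NCR distribution at its quartiles.

    Level ``Lk`` admits candidates with rank at most
    ``(q_{k+1} - 1) * n_known``, followed by sex-matching of the new cases
    to the known-case sex proportions (down-sampling the over-represented
    sex, keeping the highest-probability candidates first). Known cases
    belong to every level, so L0 through L3 are nested by construction.
    """
    known = np.sort(np.asarray(list(known_case_ids)))
    sex_by_eid = participants.set_index("eid")["sex"]
    female_frac = float((sex_by_eid.loc[known] == "F").mean())

    tab = ranked.table
    ncr = np.clip(tab["ncr"].to_numpy(), 1.0, NCR_MAX) if len(tab) else np.array([])
    levels: dict[str, np.ndarray] = {}
    new_cases: dict[str, np.ndarray] = {}
    cuts: dict[str, float] = {}
    for k, level in enumerate(LEVELS):
        if ncr.size == 0:
            cuts[f"q{k + 1}"] = 1.0
            new_cases[level] = np.array([], dtype=known.dtype)
            levels[level] = known
            continue
        q = float(np.quantile(ncr, 0.25 * (k + 1)))
        cuts[f"q{k + 1}"] = q
        max_rank = int(np.floor((q - 1.0) * ranked.n_known + 1e-9))
        pool = tab.loc[tab["rank"] <= max_rank]
        kept = _sex_matched_subset(pool, sex_by_eid, female_frac)
        new_cases[level] = np.sort(kept)
        levels[level] = np.sort(np.concatenate([known, kept]))
    return AugmentedCohorts(
        icd10=icd10, levels=levels, new_cases=new_cases,
        cut_points=cuts, n_known=ranked.n_known,
    )


def capped_table_test(
    diagnosed_after: np.ndarray, predicted_positive: np.ndarray
) -> CappedValidationResult:
    """One-sided Fisher test of the 2x2 (post-cutoff diagnosis x prediction).

    ``a`` counts post-cutoff cases predicted positive. The odds ratio is
    the cross-product ratio with Haldane +0.5 correction only when a cell
    is empty.
    """
    diagnosed_after = np.asarray(diagnosed_after, bool)
    predicted_positive = np.asarray(predicted_positive, bool)
    a = int((diagnosed_after & predicted_positive).sum())
    b = int((diagnosed_after & ~predicted_positive).sum())
    c = int((~diagnosed_after & predicted_positive).sum())
    d = int((~diagnosed_after & ~predicted_positive).sum())
    table = np.array([[a, b], [c, d]])
    _, p = fisher_exact(table, alternative="greater")
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return CappedValidationResult(
        cutoff_date=pd.NaT, threshold=np.nan,
        table=table, odds_ratio=float(odds), p_value=float(p),
    )


def capped_validation(
    biobank,
    icd10: str,
    cutoff_date,
    threshold: float = 0.7,
    time_model: TimeModelSpec = TimeModelSpec("prognostic", 10),
    feature_specs=None,
    ensemble_config=None,
    ctrl_ratio_max: int = 9,
    seed: int = 0,
    min_cases: int = 20,
) -> CappedValidationResult:
    """Temporal hold-out validation of the disease-signature model.

    The model is trained only on cases diagnosed strictly before
    ``cutoff_date``; every participant outside the training case set is
    then scored, and the 2x2 table of (first qualifying diagnosis on/after
    cutoff) against (mean probability >= threshold) is tested one-sided.
    """
    from .ensemble import DiseaseSignatureModel, EnsembleConfig
    from .preprocess import Preprocessor
    from .specs import FeatureSpec

    cutoff = pd.Timestamp(cutoff_date)
    diag = biobank.diagnoses
    codes = descendant_codes(icd10, biobank.hierarchy)
    qualifying = diag.loc[diag["icd10"].isin(codes)]
    post_ids = set(qualifying.loc[pd.to_datetime(qualifying["diag_date"]) >= cutoff, "eid"])
    if not post_ids:
        raise ValueError(f"{icd10}: no diagnoses on/after {cutoff.date()}")

    pre_diag = diag.loc[pd.to_datetime(diag["diag_date"]) < cutoff]
    case_set = collect_cases(pre_diag, biobank.hierarchy, biobank.participants, icd10)
    case_set = apply_time_model(case_set, time_model)
    if case_set.n_cases < min_cases:
        raise ValueError(f"{icd10}: only {case_set.n_cases} pre-cutoff cases")
    cohort = select_controls(
        case_set, biobank.participants, pre_diag, biobank.hierarchy,
        ctrl_ratio_max=ctrl_ratio_max, seed=seed, require_eligible=False,
    )

    if feature_specs is None:
        feature_specs = ([FeatureSpec(name=n) for n in biobank.feature_names()]
                         + [FeatureSpec(name="sex", role="categorical"),
                            FeatureSpec(name="age", role="covariate")])
    table = biobank.biomarkers.merge(
        biobank.participants[["eid", "sex", "age"]], on="eid"
    ).set_index("eid")
    prep = Preprocessor(feature_specs)
    train_ids = np.concatenate([cohort.case_ids, cohort.control_ids])
    prep.fit(table.loc[train_ids])
    mat, cols = prep.transform(table)
    features = pd.DataFrame(mat, index=table.index, columns=cols)

    config = ensemble_config or EnsembleConfig(base_seed=seed)
    results = DiseaseSignatureModel(features, cohort, config).fit()

    train_cases = set(cohort.case_ids)
    evaluable = biobank.participants.loc[
        ~biobank.participants["eid"].isin(train_cases), "eid"
    ].to_numpy()
    probs = results.predictions.loc[evaluable]
    diagnosed_after = np.array([e in post_ids for e in evaluable])
    out = capped_table_test(diagnosed_after, (probs >= threshold).to_numpy())
    out.cutoff_date = cutoff
    out.threshold = threshold
    return out
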