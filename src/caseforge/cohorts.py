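"""Case and matched-control cohort definition per ICD10 code.

Cases are collected across every diagnosis source and every descendant of
the queried code; a phenotype is eligible when it has at least 100 known
cases. Cases may then be filtered by one of three time-models relating the
biomarker collection date to the diagnosis date — prognostic (diagnosed
0..t years after collection), diagnostic (0..t years before, inclusive on
both ends) or time-agnostic — and by a sex-specificity rule that drops
minority-sex cases when one sex holds more than 90% of the phenotype.

Controls are drawn from participants with no diagnosis anywhere in the case
code's ICD10 chapter, then sampled without replacement to match the case
distribution over four age bins crossed with sex at a fixed
controls-per-case ratio (``ctrl_ratio``, at most ``ctrl_ratio_max``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import child_rng

__all__ = [
    "TimeModelSpec",
    "CaseSet",
    "Cohort",
    "collect_cases",
    "compute_time_lag",
    "apply_time_model",
    "apply_sex_filter",
    "select_controls",
    "descendant_codes",
    "chapter_of",
    "MIN_CASES",
]

MIN_CASES = 100

_KINDS = ("time-agnostic", "prognostic", "diagnostic")


@dataclass(frozen=True)
class TimeModelSpec:
    kind: str = "time-agnostic"
    lag_years: int = 10

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.lag_years < 0:
            raise ValueError("lag_years must be non-negative")


@dataclass
class CaseSet:
    """Cases for one ICD10 code with per-case signed time-lags (years)."""

    icd10: str
    table: pd.DataFrame  # columns: eid, lag_years
    sex_filtered: bool = False

    @property
    def case_ids(self) -> np.ndarray:
        return self.table["eid"].to_numpy()

    @property
    def n_cases(self) -> int:
        return len(self.table)

    @property
    def eligible(self) -> bool:
        return self.n_cases >= MIN_CASES


@dataclass
class Cohort:
    """Matched case/control cohort for one phenotype."""

    icd10: str
    case_ids: np.ndarray
    control_ids: np.ndarray
    ctrl_ratio: int
    age_bin_edges: np.ndarray
    matching: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        overlap = set(self.case_ids) & set(self.control_ids)
        if overlap:
            raise ValueError(f"case/control overlap: {sorted(overlap)[:5]}...")


def chapter_of(icd10: str, hierarchy: pd.DataFrame) -> str:
    row = hierarchy.loc[hierarchy["code"] == icd10]
    if row.empty:
        raise KeyError(f"ICD10 code {icd10!r} not present in hierarchy")
    return row["chapter"].iloc[0]


def descendant_codes(icd10: str, hierarchy: pd.DataFrame) -> set[str]:
    """The code itself plus all its sub-nodes per the parent pointers."""
    if not (hierarchy["code"] == icd10).any():
        raise KeyError(f"ICD10 code {icd10!r} not present in hierarchy")
    children: dict[str, list[str]] = {}
    for code, parent in zip(hierarchy["code"], hierarchy["parent"].fillna("")):
        if parent:
            children.setdefault(parent, []).append(code)
    out = {icd10}
    frontier = [icd10]
    while frontier:
        node = frontier.pop()
        for ch in children.get(node, []):
            if ch not in out:
                out.add(ch)
                frontier.append(ch)
    return out


def compute_time_lag(collection_date, diagnosis_date) -> int:
    """Signed lag in whole years: round(days / 365), half away from zero.

    Positive means the diagnosis came after biomarker sample collection.
    """
    days = (pd.Timestamp(diagnosis_date) - pd.Timestamp(collection_date)).days
    years = days / 365.0
    return int(np.sign(years) * np.floor(abs(years) + 0.5))


def collect_cases(
    diagnoses: pd.DataFrame,
    hierarchy: pd.DataFrame,
    participants: pd.DataFrame,
    icd10: str,
) -> CaseSet:
    """Union of participants diagnosed with ``icd10`` or any sub-node.

    Each participant appears once; when several qualifying diagnoses exist
    the one with the shortest absolute time-lag is retained.
    """
    codes = descendant_codes(icd10, hierarchy)
    hits = diagnoses.loc[diagnoses["icd10"].isin(codes), ["eid", "diag_date"]]
    if hits.empty:
        return CaseSet(icd10, pd.DataFrame({"eid": pd.Series(dtype=np.int64),
                                            "lag_years": pd.Series(dtype=int)}))
    coll = participants.set_index("eid")["collection_date"]
    hits = hits.merge(coll.rename("collection_date"), left_on="eid", right_index=True)
    days = (pd.to_datetime(hits["diag_date"]) - pd.to_datetime(hits["collection_date"])).dt.days
    years = days / 365.0
    hits = hits.assign(
        lag_years=(np.sign(years) * np.floor(np.abs(years) + 0.5)).astype(int)
    )
    hits["abs_lag"] = hits["lag_years"].abs()
    best = (
        hits.sort_values(["eid", "abs_lag", "lag_years"], kind="stable")
        .drop_duplicates("eid", keep="first")
        .sort_values("eid")
        .reset_index(drop=True)
    )
    return CaseSet(icd10, best[["eid", "lag_years"]])


def apply_time_model(case_set: CaseSet, spec: TimeModelSpec) -> CaseSet:
    """Restrict cases to the time-model's lag window (bounds inclusive)."""
    t = case_set.table
    if spec.kind == "time-agnostic":
        kept = t
    elif spec.kind == "prognostic":
        kept = t.loc[(t["lag_years"] >= 0) & (t["lag_years"] <= spec.lag_years)]
    else:  # diagnostic
        kept = t.loc[(t["lag_years"] >= -spec.lag_years) & (t["lag_years"] <= 0)]
    return CaseSet(case_set.icd10, kept.reset_index(drop=True), case_set.sex_filtered)


def apply_sex_filter(
    case_set: CaseSet, participants: pd.DataFrame, threshold: float = 0.9
) -> CaseSet:
    """Drop minority-sex cases when one sex exceeds ``threshold`` of cases."""
    t = case_set.table
    if t.empty:
        return case_set
    sex = participants.set_index("eid")["sex"]
    case_sex = t["eid"].map(sex)
    frac_f = float((case_sex == "F").mean())
    dominant = "F" if frac_f >= 0.5 else "M"
    if max(frac_f, 1.0 - frac_f) > threshold:
        kept = t.loc[(case_sex == dominant).to_numpy()].reset_index(drop=True)
        return CaseSet(case_set.icd10, kept, sex_filtered=True)
    return case_set


def potential_controls(
    participants: pd.DataFrame,
    diagnoses: pd.DataFrame,
    hierarchy: pd.DataFrame,
    icd10: str,
) -> np.ndarray:
    """Participants without any diagnosis in the chapter of ``icd10``."""
    chap = chapter_of(icd10, hierarchy)
    chap_codes = set(hierarchy.loc[hierarchy["chapter"] == chap, "code"])
    # diagnoses may reference codes absent from the hierarchy table; those
    # are assigned to a chapter by their leading letter
    from .biobank import icd10_chapter

    in_chapter = diagnoses["icd10"].map(
        lambda c: c in chap_codes or icd10_chapter(c) == chap
    )
    diagnosed = set(diagnoses.loc[in_chapter, "eid"])
    mask = ~participants["eid"].isin(diagnosed)
    return participants.loc[mask, "eid"].to_numpy()


def select_controls(
    case_set: CaseSet,
    participants: pd.DataFrame,
    diagnoses: pd.DataFrame,
    hierarchy: pd.DataFrame,
    ctrl_ratio_max: int = 19,
    seed: int = 0,
    require_eligible: bool = True,
) -> Cohort:
    """Sample matched controls at an integer controls-per-case ratio.

    Age is split at the quartile edges of the case age distribution; within
    each (age bin, sex) cell, ``ctrl_ratio`` controls per case are sampled
    without replacement from the chapter-excluded pool. The achieved ratio
    is the largest integer ``<= ctrl_ratio_max`` every cell can supply;
    cases are dropped from cells whose control supply cannot cover them.
    """
    if require_eligible and not case_set.eligible:
        raise ValueError(
            f"{case_set.icd10}: {case_set.n_cases} cases < {MIN_CASES} required"
        )
    pool = potential_controls(participants, diagnoses, hierarchy, case_set.icd10)
    pool = np.setdiff1d(pool, case_set.case_ids)
    if pool.size == 0:
        raise ValueError(f"{case_set.icd10}: no potential controls remain")

    info = participants.set_index("eid")
    case_ids = np.sort(case_set.case_ids)
    case_age = info.loc[case_ids, "age"].to_numpy(float)
    case_sex = info.loc[case_ids, "sex"].to_numpy()
    edges = np.quantile(case_age, [0.0, 0.25, 0.5, 0.75, 1.0])
    edges = np.unique(edges)
    if edges.size < 2:
        edges = np.array([edges[0] - 0.5, edges[0] + 0.5])
    edges[0], edges[-1] = -np.inf, np.inf

    def binify(ages: np.ndarray) -> np.ndarray:
        return np.clip(np.searchsorted(edges, ages, side="right") - 1,
                       0, edges.size - 2)

    case_bin = binify(case_age)
    pool_sorted = np.sort(pool)
    pool_age = info.loc[pool_sorted, "age"].to_numpy(float)
    pool_sex = info.loc[pool_sorted, "sex"].to_numpy()
    pool_bin = binify(pool_age)

    rng = child_rng(seed, "select_controls", case_set.icd10)
    cells = sorted({(b, s) for b, s in zip(case_bin, case_sex)})
    supply = {}
    demand = {}
    for b, s in cells:
        supply[(b, s)] = np.flatnonzero((pool_bin == b) & (pool_sex == s))
        demand[(b, s)] = int(((case_bin == b) & (case_sex == s)).sum())

    # drop cases from cells whose supply cannot cover even one control each
    kept_case_mask = np.ones(case_ids.size, dtype=bool)
    for (b, s) in cells:
        short = demand[(b, s)] - supply[(b, s)].size
        if short > 0:
            cell_idx = np.flatnonzero((case_bin == b) & (case_sex == s))
            drop = rng.permutation(cell_idx)[:short]
            kept_case_mask[drop] = False
            demand[(b, s)] -= short
    cells = [c for c in cells if demand[c] > 0]
    if not cells:
        raise ValueError(f"{case_set.icd10}: control matching left no cases")

    ratio = int(min(ctrl_ratio_max,
                    min(supply[c].size // demand[c] for c in cells)))
    ratio = max(ratio, 0)
    if ratio == 0:
        raise ValueError(f"{case_set.icd10}: zero achievable control ratio")

    control_idx = []
    rows = []
    for (b, s) in cells:
        take = ratio * demand[(b, s)]
        chosen = rng.permutation(supply[(b, s)])[:take]
        control_idx.append(chosen)
        rows.append((b, s, demand[(b, s)], take))
    control_ids = np.sort(pool_sorted[np.concatenate(control_idx)])
    matching = pd.DataFrame(rows, columns=["age_bin", "sex", "n_cases", "n_controls"])

    return Cohort(
        icd10=case_set.icd10,
        case_ids=case_ids[kept_case_mask],
        control_ids=control_ids,
        ctrl_ratio=ratio,
        age_bin_edges=edges,
        matching=matching,
    )
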