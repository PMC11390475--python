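"""Rare-variant collapsing PheWAS, pan-ancestry combination and hit triage.

Binary collapsing tests compare qualifying-variant (QV) carrier counts
between cases and controls per gene with a two-sided Fisher exact test;
genes with p below 1e-8 are genome-wide significant. Sixteen genes known to
carry clonal somatic mutations in blood (clonal hematopoiesis) are excluded
by default because their apparent carriers can be somatic artefacts.

Hits found in augmented cohorts are triaged into three classes:

* known-binary   — already significant in the baseline cohort with the
  same direction of effect;
* known-quant    — a dominating biomarker of the phenotype (FIZ > 1.2) is
  itself genome-wide significant for the gene in a quantitative PheWAS,
  i.e. the hit may reflect a biomarker correlation;
* putative-novel — significant only in the augmented cohorts with no
  dominating-biomarker explanation.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import fisher_exact
from statsmodels.stats.contingency_tables import StratifiedTable

from ._seeds import child_rng

__all__ = [
    "AssociationResult",
    "binary_collapsing_test",
    "run_phewas",
    "quantitative_collapsing_test",
    "cmh_pan_ancestry",
    "classify_hits",
    "load_chip_exclusion_genes",
    "sex_matched_controls",
]

GENOME_WIDE_P = 1e-8


def load_chip_exclusion_genes() -> list[str]:
    """Genes excluded for clonal-hematopoiesis somatic-variant contamination."""
    text = resources.files("caseforge.data").joinpath("chip_genes.txt").read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


@dataclass
class AssociationResult:
    gene: str
    icd10: str
    qv_model: str
    level: str
    a: int  # case carriers
    b: int  # case non-carriers
    c: int  # control carriers
    d: int  # control non-carriers
    odds_ratio: float
    p_value: float
    direction: int  # sign of log OR; 0 when undefined
    haldane: bool = False


def binary_collapsing_test(
    case_ids,
    control_ids,
    carrier_ids,
    gene: str = "",
    icd10: str = "",
    qv_model: str = "",
    level: str = "baseline",
) -> AssociationResult:
    """Two-sided Fisher exact test on the case/control x carrier table.

    The odds ratio is the cross-product ratio ``ad / bc``; when any cell is
    zero the Haldane +0.5 correction is applied to every cell and the
    result flagged.
    """
    cases = set(case_ids)
    controls = set(control_ids)
    if not cases or not controls:
        raise ValueError("empty case or control set")
    carriers = set(carrier_ids)
    a = len(cases & carriers)
    b = len(cases) - a
    c = len(controls & carriers)
    d = len(controls) - c
    _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    haldane = min(a, b, c, d) == 0
    if haldane:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    if a + c == 0:
        direction = 0  # no carriers anywhere: direction undefined
    else:
        direction = int(np.sign(np.log(odds))) if odds != 1 else 0
    return AssociationResult(gene, icd10, qv_model, level, a, b, c, d,
                             float(odds), float(p), direction, haldane)


def sex_matched_controls(
    control_pool: np.ndarray,
    case_ids: np.ndarray,
    participants: pd.DataFrame,
    seed: int = 0,
) -> np.ndarray:
    """Down-sample a control pool to the case sex proportions."""
    sex = participants.set_index("eid")["sex"]
    case_sex = sex.loc[np.asarray(case_ids)]
    p_f = float((case_sex == "F").mean())
    pool = np.sort(np.asarray(control_pool))
    pool_sex = sex.loc[pool].to_numpy()
    females = pool[pool_sex == "F"]
    males = pool[pool_sex == "M"]
    if p_f >= 1.0:
        return females
    if p_f <= 0.0:
        return males
    total = min(int(np.floor(len(females) / p_f)),
                int(np.floor(len(males) / (1.0 - p_f))))
    keep_f = min(int(round(p_f * total)), len(females))
    keep_m = min(total - keep_f, len(males))
    rng = child_rng(seed, "sex-match-controls")
    chosen = np.concatenate([
        rng.permutation(females)[:keep_f],
        rng.permutation(males)[:keep_m],
    ])
    return np.sort(chosen)


def run_phewas(
    cohorts_by_level: dict[str, np.ndarray],
    control_pool: np.ndarray,
    carriers: pd.DataFrame,
    participants: pd.DataFrame,
    icd10: str = "",
    exclusions: list[str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Collapsing tests for every (gene, qv_model, cohort level).

    ``control_pool`` should already exclude chapter-diagnosed participants;
    per level, the pool minus that level's cases is re-matched to the
    level's case sex distribution by down-sampling.
    """
    if exclusions is None:
        exclusions = load_chip_exclusion_genes()
    excluded = set(exclusions)
    rows = []
    gene_groups = carriers.groupby(["gene", "qv_model"])["eid"].apply(set)
    for level, case_ids in cohorts_by_level.items():
        pool = np.setdiff1d(np.asarray(control_pool), np.asarray(case_ids))
        ctrl = sex_matched_controls(pool, np.asarray(case_ids), participants,
                                    seed=seed)
        for (gene, qv_model), carrier_set in gene_groups.items():
            if gene in excluded:
                continue
            res = binary_collapsing_test(
                case_ids, ctrl, carrier_set,
                gene=gene, icd10=icd10, qv_model=qv_model, level=level,
            )
            rows.append(res.__dict__)
    return pd.DataFrame(rows)


def min_p_summary(assoc: pd.DataFrame) -> pd.DataFrame:
    """Per (gene, icd10): the configuration with the lowest p value."""
    idx = assoc.groupby(["gene", "icd10"])["p_value"].idxmin()
    return assoc.loc[idx].reset_index(drop=True)


def quantitative_collapsing_test(
    biomarker: pd.Series,
    carrier_ids,
    participants: pd.DataFrame,
) -> tuple[float, float]:
    """OLS of a biomarker on carrier status adjusting for sex and age.

    Returns ``(effect, p)`` for the carrier coefficient (two-sided).
    A constant biomarker yields ``(0.0, 1.0)``.
    """
    info = participants.set_index("eid")
    eids = biomarker.dropna().index
    y = biomarker.loc[eids].to_numpy(float)
    carrier = np.isin(np.asarray(eids), np.asarray(list(carrier_ids))).astype(float)
    if carrier.sum() < 2:
        raise ValueError("need at least 2 carriers with non-missing biomarker")
    if np.ptp(y) == 0:
        return 0.0, 1.0
    X = pd.DataFrame({
        "carrier": carrier,
        "sex": (info.loc[eids, "sex"] == "F").to_numpy(float),
        "age": info.loc[eids, "age"].to_numpy(float),
    })
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    return float(fit.params["carrier"]), float(fit.pvalues["carrier"])


def cmh_pan_ancestry(tables: list[np.ndarray]) -> tuple[float, float, float]:
    """Cochran-Mantel-Haenszel combination of per-ancestry 2x2 tables.

    Returns ``(statistic, p, common_odds_ratio)`` using the 1-df chi-square
    without continuity correction and the Mantel-Haenszel pooled OR.
    Strata with an empty margin contribute nothing and are dropped.
    """
    kept = []
    for t in tables:
        t = np.asarray(t, float)
        if t.shape != (2, 2):
            raise ValueError("each stratum must be a 2x2 table")
        if t.sum(axis=0).min() > 0 and t.sum(axis=1).min() > 0:
            kept.append(t)
    if not kept:
        raise ValueError("all strata are degenerate")
    st = StratifiedTable(np.stack(kept, axis=-1))
    res = st.test_null_odds(correction=False)
    return float(res.statistic), float(res.pvalue), float(st.oddsratio_pooled)


def classify_hits(
    milton_table: pd.DataFrame,
    baseline_table: pd.DataFrame,
    quant_table: pd.DataFrame,
    fiz_by_icd10: dict[str, pd.DataFrame],
    sig_threshold: float = GENOME_WIDE_P,
    fiz_threshold: float = 1.2,
) -> pd.DataFrame:
    """Triage augmented-cohort hits per (gene, icd10).

    ``milton_table``/``baseline_table`` are collapsing results (one row per
    gene/icd10 after min-p reduction) with ``p_value`` and ``direction``.
    ``quant_table`` has columns (gene, feature, p_value) from the
    quantitative PheWAS. ``fiz_by_icd10`` maps icd10 to its FIZ table
    (indexed by feature with a ``dominating`` column).
    """
    base = baseline_table.set_index(["gene", "icd10"])
    rows = []
    for _, hit in milton_table.iterrows():
        key = (hit["gene"], hit["icd10"])
        if hit["p_value"] >= sig_threshold:
            continue
        fiz = fiz_by_icd10.get(hit["icd10"])
        if fiz is None:
            raise ValueError(f"no FIZ table for {hit['icd10']}; cannot triage")
        label = "putative-novel"
        if key in base.index:
            b = base.loc[key]
            if (b["p_value"] < sig_threshold
                    and b["direction"] == hit["direction"]):
                label = "known-binary"
        if label != "known-binary":
            dom = set(fiz.index[fiz["dominating"]])
            gq = quant_table.loc[
                (quant_table["gene"] == hit["gene"])
                & (quant_table["feature"].isin(dom))
            ]
            if (gq["p_value"] < sig_threshold).any():
                label = "known-quant"
        rows.append({
            "gene": hit["gene"], "icd10": hit["icd10"],
            "qv_model": hit.get("qv_model", ""), "level": hit.get("level", ""),
            "p_value": hit["p_value"], "odds_ratio": hit.get("odds_ratio", np.nan),
            "direction": hit["direction"], "label": label,
        })
    return pd.DataFrame(rows)
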