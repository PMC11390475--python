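"""Ranked-list enrichment, comorbidity scoring and signature uniqueness.

The stepwise hypergeometric test walks down a ranked gene list, testing the
overlap of each prefix with a known gene set by a one-sided Fisher
(hypergeometric tail) test; the resulting p-value sequence is transformed
to ``max(-10 log10(0.05), -10 log10 p)`` and summarized by the area of the
curve above the 0.05 floor, normalized by list length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, hypergeom

__all__ = [
    "EnrichmentCurve",
    "stepwise_hypergeometric",
    "comorbidity_enrichment",
    "signature_uniqueness",
]

FLOOR = -10.0 * np.log10(0.05)


@dataclass
class EnrichmentCurve:
    p_values: np.ndarray  # per prefix length 1..len(ranked)
    curve: np.ndarray  # max(floor, -10 log10 p)
    auc: float  # mean area above the floor
    universe_size: int


def stepwise_hypergeometric(
    ranked_genes: list[str],
    known_set,
    universe,
) -> EnrichmentCurve:
    """Prefix-wise over-representation of ``known_set`` in a ranked list."""
    universe = set(universe)
    known = set(known_set)
    if not known:
        raise ValueError("known gene set is empty")
    if not known <= universe:
        raise ValueError("known set must be contained in the universe")
    if not set(ranked_genes) <= universe:
        raise ValueError("ranked genes must be contained in the universe")
    M = len(universe)
    K = len(known)
    ps = np.empty(len(ranked_genes))
    overlap = 0
    for i, gene in enumerate(ranked_genes):
        if gene in known:
            overlap += 1
        n = i + 1
        # one-sided tail: P(X >= overlap) for X ~ Hypergeom(M, K, n)
        ps[i] = hypergeom.sf(overlap - 1, M, K, n)
    curve = np.maximum(FLOOR, -10.0 * np.log10(ps))
    auc = float((curve - FLOOR).mean()) if curve.size else 0.0
    return EnrichmentCurve(p_values=ps, curve=curve, auc=auc, universe_size=M)


def comorbidity_enrichment(
    cohort_ids,
    diagnoses: pd.DataFrame,
    universe_ids,
    cap: float = float(np.log(100.0)),
) -> pd.DataFrame:
    """Score every ICD10 code diagnosed in the cohort for over-incidence.

    Per code, a 2x2 of (cohort vs rest of the universe) x (diagnosed vs
    not) is tested by Fisher's exact test; the score is the log odds ratio
    capped at ``cap``, floored at 0, and normalized to [0, 100].
    """
    cohort = set(cohort_ids)
    universe = set(universe_ids)
    if not cohort <= universe:
        raise ValueError("cohort must be a subset of the universe")
    n_cohort = len(cohort)
    n_rest = len(universe) - n_cohort
    rel = diagnoses.loc[diagnoses["eid"].isin(universe)]
    rows = []
    for code, grp in rel.groupby("icd10"):
        diagnosed = set(grp["eid"])
        in_cohort = len(diagnosed & cohort)
        if in_cohort == 0:
            continue
        in_rest = len(diagnosed) - in_cohort
        table = [[in_cohort, n_cohort - in_cohort],
                 [in_rest, n_rest - in_rest]]
        odds, p = fisher_exact(table)
        if not np.isfinite(odds) or odds <= 0:
            log_or = cap if odds > 1 or not np.isfinite(odds) else 0.0
        else:
            log_or = np.log(odds)
        score = 100.0 * min(max(log_or, 0.0), cap) / cap
        rows.append((code, float(odds), float(p), float(score)))
    out = pd.DataFrame(rows, columns=["icd10", "odds_ratio", "p_value", "score"])
    return out.sort_values("score", ascending=False).reset_index(drop=True)


def _top_n(fis: pd.Series, n: int) -> frozenset:
    ordered = fis.sort_values(ascending=False, kind="stable")
    # ties broken by feature name for a deterministic signature
    ordered = fis.iloc[
        np.lexsort((np.asarray(fis.index, dtype=object), -fis.to_numpy()))
    ]
    return frozenset(ordered.index[:n])


def signature_uniqueness(fis_tables: dict[str, pd.Series], n: int) -> int:
    """Number of phenotypes whose top-``n`` feature set is shared.

    Counts phenotypes whose top-``n`` FIS features (ties broken by feature
    name) coincide exactly with those of at least one other phenotype.
    """
    if len(fis_tables) < 2:
        raise ValueError("need at least 2 phenotypes")
    for name, fis in fis_tables.items():
        if n > len(fis):
            raise ValueError(f"top-{n} exceeds feature count for {name}")
    tops = {name: _top_n(fis, n) for name, fis in fis_tables.items()}
    counts: dict[frozenset, int] = {}
    for sig in tops.values():
        counts[sig] = counts.get(sig, 0) + 1
    return sum(1 for sig in tops.values() if counts[sig] > 1)
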