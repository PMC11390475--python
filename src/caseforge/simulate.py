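"""Synthetic biobank generator with planted, fully known ground truth.

The generative model, per disease ``d``:

1.  Every participant carries a latent severity factor ``z ~ N(0, 1)``.
2.  Liability is Bernoulli with ``p = sigmoid(alpha_sex + w * z + sum_g
    log(m_gd) * carrier_g)`` where ``m_gd`` is the planted liability odds
    multiplier of gene ``g`` for disease ``d``. The sex-specific intercepts
    ``alpha_sex`` are calibrated by bisection so that the realized overall
    prevalence matches ``DiseaseSpec.prevalence`` and the female share of
    liability-positive participants matches ``sex_bias``.
3.  Every liability-positive participant receives a latent diagnosis date,
    offset from the biomarker collection date by a normal lag
    (``lag_mean_days``, ``lag_sd_days``); positive lags mean diagnosis
    after sample collection.
4.  Affected biomarkers of liability-positive participants are shifted by
    ``pre_diagnosis_shift`` SD when the sample predates the diagnosis
    (lag > 0) and by ``post_diagnosis_shift`` SD otherwise.
5.  A ``cryptic_fraction`` of liability-positive participants has the
    diagnosis record withheld while keeping the shifted biomarkers — these
    are the cryptic cases downstream augmentation should recover.

Missingness is applied block-wise per assay panel (all-or-none per
participant) plus per-feature MCAR, mimicking the correlated missingness of
assay batteries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._seeds import child_rng
from .biobank import Biobank, TruthManifest, icd10_chapter
from .specs import ConfigError, DiseaseSpec, SimConfig

__all__ = ["generate_biobank", "inject_cryptic_cases"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _calibrate_intercept(eta: np.ndarray, target_rate: float) -> float:
    """Bisection for the intercept making ``mean(sigmoid(a + eta))`` hit target."""
    lo, hi = -30.0, 30.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _sigmoid(mid + eta).mean() < target_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_biobank(config: SimConfig) -> tuple[Biobank, TruthManifest]:
    """Draw one synthetic biobank. Deterministic given ``config.seed``."""
    n = config.n_participants
    seed = config.seed

    # --- participants ------------------------------------------------------
    rng = child_rng(seed, "participants")
    eids = np.arange(1_000_000, 1_000_000 + n)
    sex = np.where(rng.random(n) < config.female_fraction, "F", "M")
    lo_age, hi_age = config.age_range
    age = np.clip(np.round(rng.normal(57.0, 8.0, n)), lo_age, hi_age).astype(int)
    anc_names = list(config.ancestry_fractions)
    anc_p = np.asarray([config.ancestry_fractions[a] for a in anc_names], float)
    ancestry = rng.choice(anc_names, size=n, p=anc_p / anc_p.sum())
    start = pd.Timestamp(config.date_window[0])
    end = pd.Timestamp(config.date_window[1])
    span = (end - start).days
    collection = start + pd.to_timedelta(rng.integers(0, span + 1, n), unit="D")
    participants = pd.DataFrame(
        {"eid": eids, "sex": sex, "age": age, "ancestry": ancestry,
         "collection_date": collection}
    )

    # --- carriers ----------------------------------------------------------
    carrier_flags: dict[tuple[str, str], np.ndarray] = {}
    carrier_rows = []
    for g in config.genes:
        grng = child_rng(seed, "carriers", g.gene, g.qv_model)
        flag = grng.random(n) < g.carrier_freq
        carrier_flags[(g.gene, g.qv_model)] = flag
        for e in eids[flag]:
            carrier_rows.append((g.gene, g.qv_model, e))
    carriers = pd.DataFrame(carrier_rows, columns=["gene", "qv_model", "eid"])

    # --- biomarker base values --------------------------------------------
    # sex and age live on the participants table; the biomarker table holds
    # only measured features
    xrng = child_rng(seed, "biomarkers")
    measured = [f for f in config.features
                if f.name not in ("sex", "age") and f.role != "categorical"]
    values = {
        f.name: f.mean + f.sd * xrng.standard_normal(n) for f in measured
    }

    # --- per-disease liability, diagnosis dates, biomarker shifts ----------
    is_female = sex == "F"
    status_rows = []
    diag_rows = []
    source_pool = np.array(["hes", "death", "cancer"])
    for d in config.diseases:
        drng = child_rng(seed, "disease", d.icd10)
        z = drng.standard_normal(n)
        eta = config.liability_weight * z
        for g in config.genes:
            m = g.odds_multiplier.get(d.icd10)
            if m is not None:
                eta = eta + np.log(m) * carrier_flags[(g.gene, g.qv_model)]

        n_f = int(is_female.sum())
        n_m = n - n_f
        liability = np.zeros(n, dtype=bool)
        for female, count, share in ((True, n_f, d.sex_bias),
                                     (False, n_m, 1.0 - d.sex_bias)):
            mask = is_female == female
            if count == 0:
                continue
            rate = min(max(d.prevalence * n * share / count, 1e-9), 1 - 1e-9)
            alpha = _calibrate_intercept(eta[mask], rate)
            liability[mask] = drng.random(count) < _sigmoid(alpha + eta[mask])

        lag_days = np.round(
            drng.normal(d.lag_mean_days, d.lag_sd_days, n)
        ).astype(int)
        diag_dates = collection + pd.to_timedelta(lag_days, unit="D")
        sources = source_pool[drng.integers(0, 3, n)]

        # biomarker shifts: pre-diagnosis when the sample predates diagnosis
        for name, (pre, post) in d.affected_features.items():
            if name not in values:
                raise ConfigError(f"affected feature {name!r} not in feature list")
            spec = next(f for f in config.features if f.name == name)
            shift = np.where(lag_days > 0, pre, post) * spec.sd
            values[name] = values[name] + np.where(liability, shift, 0.0)

        for i in np.flatnonzero(liability):
            diag_rows.append((eids[i], d.icd10, diag_dates[i], sources[i]))
        status_rows.append(pd.DataFrame({
            "eid": eids,
            "icd10": d.icd10,
            "liability": liability,
            "diagnosed": liability,
            "cryptic": False,
            "latent_lag_days": np.where(liability, lag_days, np.nan),
        }))

    diagnoses = pd.DataFrame(diag_rows, columns=["eid", "icd10", "diag_date", "source"])
    if diagnoses.empty:
        diagnoses = pd.DataFrame(
            {"eid": pd.Series(dtype=np.int64), "icd10": pd.Series(dtype=str),
             "diag_date": pd.Series(dtype="datetime64[ns]"),
             "source": pd.Series(dtype=str)}
        )
    status = (
        pd.concat(status_rows, ignore_index=True)
        if status_rows
        else pd.DataFrame(columns=["eid", "icd10", "liability", "diagnosed",
                                   "cryptic", "latent_lag_days"])
    )

    # --- missingness: block-wise per panel, then per-feature MCAR ----------
    mrng = child_rng(seed, "missingness")
    panels: dict[str, list[str]] = {}
    for f in measured:
        panels.setdefault(f.panel, []).append(f.name)
    biomarkers = pd.DataFrame({"eid": eids} | values)
    for panel, names in panels.items():
        rate = config.panel_missing_rate.get(panel, 0.0)
        if rate > 0:
            block = mrng.random(n) < rate
            biomarkers.loc[block, names] = np.nan
    for f in measured:
        if f.missing_rate > 0:
            miss = mrng.random(n) < f.missing_rate
            biomarkers.loc[miss, f.name] = np.nan

    hierarchy = pd.DataFrame(
        [(d.icd10, "", icd10_chapter(d.icd10)) for d in config.diseases],
        columns=["code", "parent", "chapter"],
    )

    gene_effects = pd.DataFrame(
        [(g.gene, g.qv_model, code, m)
         for g in config.genes for code, m in g.odds_multiplier.items()],
        columns=["gene", "qv_model", "icd10", "odds_multiplier"],
    )

    biobank = Biobank(participants, diagnoses, biomarkers, carriers, hierarchy)
    manifest = TruthManifest(status=status, gene_effects=gene_effects)

    # cryptic-case injection is its own seeded stage per disease
    for d in config.diseases:
        if d.cryptic_fraction > 0:
            biobank, manifest = inject_cryptic_cases(
                biobank, manifest, d, seed=seed
            )
    return biobank, manifest


def inject_cryptic_cases(
    biobank: Biobank,
    manifest: TruthManifest,
    disease: DiseaseSpec,
    seed: int,
) -> tuple[Biobank, TruthManifest]:
    """Withhold the diagnosis record of a fraction of liability-positive
    participants for ``disease``, keeping their shifted biomarkers intact.

    Returns new objects; inputs are not mutated.
    """
    if not 0.0 <= disease.cryptic_fraction < 1.0:
        raise ConfigError("cryptic_fraction must be in [0, 1)")
    if not (manifest.status["icd10"] == disease.icd10).any():
        raise ConfigError(f"disease {disease.icd10} not present in biobank")

    biobank = biobank.copy()
    status = manifest.status.copy()
    if disease.cryptic_fraction == 0.0:
        return biobank, TruthManifest(status, manifest.gene_effects.copy())

    rng = child_rng(seed, "cryptic", disease.icd10)
    mask = (status["icd10"] == disease.icd10) & status["liability"] & status["diagnosed"]
    idx = status.index[mask].to_numpy()
    hide = idx[rng.random(idx.size) < disease.cryptic_fraction]
    hidden_eids = set(status.loc[hide, "eid"])

    status.loc[hide, "diagnosed"] = False
    status.loc[hide, "cryptic"] = True

    diag = biobank.diagnoses
    drop = (diag["icd10"] == disease.icd10) & diag["eid"].isin(hidden_eids)
    biobank.diagnoses = diag.loc[~drop].reset_index(drop=True)
    return biobank, TruthManifest(status, manifest.gene_effects.copy())
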