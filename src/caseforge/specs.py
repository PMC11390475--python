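"""Configuration objects for the synthetic-biobank generator.

The generator emulates the structure of a UK-Biobank-like resource:
participants recruited in mid-to-late adulthood with a modest excess of
women, block-wise assay missingness, diseases whose biomarker signatures
differ before versus after diagnosis, and rare-variant carriers whose
liability for specific diseases is multiplicatively increased.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ConfigError(ValueError):
    """Raised when a simulation or pipeline configuration is invalid."""


@dataclass(frozen=True)
class FeatureSpec:
    """One quantitative or categorical feature (biomarker or covariate).

    Parameters
    ----------
    name : str
        Unique feature name (column in the biomarker table).
    unit : str
        Measurement unit, informational only.
    panel : str
        Assay panel; missingness is applied block-wise per panel so that a
        participant who skipped an assay is missing every feature on it.
    mean, sd : float
        Population mean and standard deviation of the simulated values.
    missing_rate : float
        Additional per-feature missing-completely-at-random rate in [0, 1].
    role : str
        ``"quantitative"``, ``"categorical"`` or ``"covariate"``.
    special_imputation : dict or None
        Optional imputation rule consumed by the preprocessor, e.g.
        ``{"kind": "constant", "value": 0.0}``,
        ``{"kind": "sex_constant", "male": 36.71, "female": 110.13}`` or
        ``{"kind": "sex_median"}``.
    """

    name: str
    unit: str = ""
    panel: str = "general"
    mean: float = 0.0
    sd: float = 1.0
    missing_rate: float = 0.0
    role: str = "quantitative"
    special_imputation: dict | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigError("feature name must be non-empty")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigError(
                f"missing_rate for {self.name!r} must be in [0, 1], "
                f"got {self.missing_rate}"
            )
        if self.sd < 0:
            raise ConfigError(f"sd for {self.name!r} must be non-negative")
        if self.role not in ("quantitative", "categorical", "covariate"):
            raise ConfigError(f"unknown role {self.role!r} for {self.name!r}")


@dataclass(frozen=True)
class DiseaseSpec:
    """One simulated disease phenotype keyed by an ICD10-style code.

    ``affected_features`` maps feature name to a pair
    ``(pre_diagnosis_shift, post_diagnosis_shift)`` in SD units: the shift a
    liability-positive participant shows when the biomarker sample was drawn
    before, respectively after, the (possibly latent) diagnosis date.
    ``cryptic_fraction`` is the fraction of liability-positive participants
    whose diagnosis record is withheld — they keep the shifted biomarkers
    but look like controls to any label-based analysis.
    """

    icd10: str
    prevalence: float
    affected_features: dict[str, tuple[float, float]] = field(default_factory=dict)
    cryptic_fraction: float = 0.0
    sex_bias: float = 0.5
    lag_mean_days: float = 0.0
    lag_sd_days: float = 1460.0

    def __post_init__(self) -> None:
        if not self.icd10:
            raise ConfigError("disease icd10 code must be non-empty")
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigError(
                f"prevalence for {self.icd10} must be in (0, 1), got {self.prevalence}"
            )
        if not 0.0 <= self.cryptic_fraction < 1.0:
            raise ConfigError(
                f"cryptic_fraction for {self.icd10} must be in [0, 1), "
                f"got {self.cryptic_fraction}"
            )
        if not 0.0 <= self.sex_bias <= 1.0:
            raise ConfigError(f"sex_bias for {self.icd10} must be in [0, 1]")
        for name, shifts in self.affected_features.items():
            pre, post = shifts
            if not (abs(pre) < float("inf") and abs(post) < float("inf")):
                raise ConfigError(f"shifts for {name} must be finite")


@dataclass(frozen=True)
class GeneSpec:
    """A gene with qualifying-variant carriers at a given population frequency.

    ``odds_multiplier`` maps an ICD10 code to the multiplicative effect of
    carrier status on the liability odds for that disease; values above 1
    enrich carriers among cases, values below 1 among controls.
    """

    gene: str
    carrier_freq: float
    qv_model: str = "ptv"
    odds_multiplier: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.carrier_freq < 0.5:
            raise ConfigError(
                f"carrier_freq for {self.gene} must be in (0, 0.5), "
                f"got {self.carrier_freq}"
            )
        for code, m in self.odds_multiplier.items():
            if not m > 0:
                raise ConfigError(f"odds multiplier for {code} must be > 0, got {m}")


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of one synthetic biobank draw."""

    n_participants: int
    seed: int
    features: tuple[FeatureSpec, ...] = ()
    diseases: tuple[DiseaseSpec, ...] = ()
    genes: tuple[GeneSpec, ...] = ()
    date_window: tuple[str, str] = ("2006-01-01", "2010-12-31")
    panel_missing_rate: dict = field(default_factory=dict)
    female_fraction: float = 0.544
    age_range: tuple[int, int] = (40, 69)
    ancestry_fractions: dict = field(default_factory=lambda: {"EUR": 1.0})
    liability_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ConfigError("n_participants must be positive")
        if not self.features:
            raise ConfigError("feature list must be non-empty")
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ConfigError("feature names must be unique")
        codes = [d.icd10 for d in self.diseases]
        if len(set(codes)) != len(codes):
            raise ConfigError("disease codes must be unique")
        gkeys = [(g.gene, g.qv_model) for g in self.genes]
        if len(set(gkeys)) != len(gkeys):
            raise ConfigError("(gene, qv_model) pairs must be unique")
        start, end = self.date_window
        if not start < end:
            raise ConfigError("date_window must be a non-empty ascending range")
        for rate in self.panel_missing_rate.values():
            if not 0.0 <= rate <= 1.0:
                raise ConfigError("panel missing rates must be in [0, 1]")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ConfigError("female_fraction must be in [0, 1]")

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.features]
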