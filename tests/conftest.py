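"""Shared fixtures: small synthetic biobanks with known ground truth."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from caseforge import DiseaseSpec, FeatureSpec, GeneSpec, SimConfig, generate_biobank


def quick_features(n: int = 6, missing_rate: float = 0.0) -> tuple[FeatureSpec, ...]:
    return tuple(
        FeatureSpec(name=f"bm{i}", mean=10.0, sd=2.0, missing_rate=missing_rate,
                    panel="p1" if i < n // 2 else "p2")
        for i in range(n)
    )


def make_config(**overrides) -> SimConfig:
    base = dict(
        n_participants=2000,
        seed=7,
        features=quick_features(),
        diseases=(DiseaseSpec(icd10="N18", prevalence=0.06,
                              affected_features={"bm0": (1.5, 2.0)}),),
        genes=(),
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def matched_biobank():
    """5,000-participant biobank with two same-chapter diseases, one other-
    chapter disease, a planted risk gene and cryptic cases."""
    config = SimConfig(
        n_participants=5000,
        seed=11,
        features=quick_features(6, missing_rate=0.01),
        diseases=(
            DiseaseSpec(icd10="N18", prevalence=0.06,
                        affected_features={"bm0": (2.0, 2.0), "bm1": (1.5, 1.5)},
                        cryptic_fraction=0.2, lag_sd_days=2500),
            DiseaseSpec(icd10="N20", prevalence=0.04),
            DiseaseSpec(icd10="E11", prevalence=0.05,
                        affected_features={"bm3": (1.0, 1.5)}),
        ),
        genes=(GeneSpec(gene="PKD1", carrier_freq=0.05,
                        odds_multiplier={"N18": 3.0}),
               GeneSpec(gene="DNMT3A", carrier_freq=0.05,
                        odds_multiplier={}),),
        panel_missing_rate={"p2": 0.03},
    )
    biobank, manifest = generate_biobank(config)
    return biobank, manifest, config


@pytest.fixture()
def toy_participants():
    """Deterministic 12-participant table for hand-checkable cohort tests."""
    return pd.DataFrame({
        "eid": np.arange(1, 13),
        "sex": ["F", "M"] * 6,
        "age": [45, 50, 55, 60, 45, 50, 55, 60, 45, 50, 55, 60],
        "ancestry": ["EUR"] * 12,
        "collection_date": pd.to_datetime(["2008-06-01"] * 12),
    })
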