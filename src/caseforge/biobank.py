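"""In-memory biobank container, ground-truth manifest and on-disk bundle I/O.

The biobank is a set of plain pandas tables mirroring the generic shape of
biobank extracts:

* ``participants`` — eid, sex, age, ancestry, collection_date
* ``diagnoses``    — eid, icd10, diag_date, source (long format)
* ``biomarkers``   — eid plus one column per feature (NaN = missing)
* ``carriers``     — gene, qv_model, eid (long format)
* ``hierarchy``    — code, parent, chapter

The :class:`TruthManifest` records, per participant and disease, the latent
liability status, whether a diagnosis record exists, and — for cryptic
cases — the withheld diagnosis date. It is the oracle every downstream test
is scored against and is never consumed by the analysis itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = ["Biobank", "TruthManifest", "write_fixture_bundle", "read_fixture_bundle"]

# Roman-numeral ICD10 chapter per leading letter (simplified single-letter map).
_CHAPTER_BY_LETTER = {
    "A": "I", "B": "I", "C": "II", "D": "III", "E": "IV", "F": "V",
    "G": "VI", "H": "VII", "I": "IX", "J": "X", "K": "XI", "L": "XII",
    "M": "XIII", "N": "XIV", "O": "XV", "P": "XVI", "Q": "XVII",
    "R": "XVIII", "S": "XIX", "T": "XIX", "Z": "XXI",
}


def icd10_chapter(code: str) -> str:
    """Chapter label for an ICD10-style code, keyed on its leading letter."""
    return _CHAPTER_BY_LETTER.get(code[:1].upper(), "XXII")


@dataclass
class Biobank:
    participants: pd.DataFrame
    diagnoses: pd.DataFrame
    biomarkers: pd.DataFrame
    carriers: pd.DataFrame
    hierarchy: pd.DataFrame

    def copy(self) -> "Biobank":
        return Biobank(
            participants=self.participants.copy(),
            diagnoses=self.diagnoses.copy(),
            biomarkers=self.biomarkers.copy(),
            carriers=self.carriers.copy(),
            hierarchy=self.hierarchy.copy(),
        )

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    def feature_names(self) -> list[str]:
        return [c for c in self.biomarkers.columns if c != "eid"]


@dataclass
class TruthManifest:
    """Ground truth of a synthetic biobank draw.

    ``status`` has one row per (eid, icd10) with columns ``liability``
    (bool), ``diagnosed`` (bool), ``cryptic`` (bool) and ``latent_lag_days``
    (diagnosis minus collection, also kept for cryptic cases).
    ``gene_effects`` has one row per (gene, qv_model, icd10) with the
    planted liability odds multiplier.
    """

    status: pd.DataFrame
    gene_effects: pd.DataFrame = field(default_factory=pd.DataFrame)

    def cryptic_ids(self, icd10: str) -> set:
        s = self.status
        mask = (s["icd10"] == icd10) & s["cryptic"]
        return set(s.loc[mask, "eid"])

    def liability_ids(self, icd10: str) -> set:
        s = self.status
        mask = (s["icd10"] == icd10) & s["liability"]
        return set(s.loc[mask, "eid"])


_TABLES = ("participants", "diagnoses", "biomarkers", "carriers", "hierarchy")
_DATE_COLS = {"participants": ["collection_date"], "diagnoses": ["diag_date"]}


def write_fixture_bundle(biobank: Biobank, manifest: TruthManifest, outdir) -> list[Path]:
    """Write the five biobank tables as TSV plus the manifest as JSON.

    Missing biomarker values are written as empty fields, never zeros, so
    the bundle round-trips losslessly through :func:`read_fixture_bundle`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name in _TABLES:
        df = getattr(biobank, name).copy()
        for col in _DATE_COLS.get(name, []):
            df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, na_rep="")
        written.append(path)

    status = manifest.status.copy()
    if "latent_lag_days" in status.columns:
        status["latent_lag_days"] = status["latent_lag_days"].astype(float)
    payload = {
        "status": status.to_dict(orient="list"),
        "gene_effects": manifest.gene_effects.to_dict(orient="list"),
    }
    mpath = outdir / "truth_manifest.json"
    mpath.write_text(json.dumps(payload, indent=1, allow_nan=True))
    written.append(mpath)
    return written


def read_fixture_bundle(indir) -> tuple[Biobank, TruthManifest]:
    """Read a bundle written by :func:`write_fixture_bundle`."""
    indir = Path(indir)
    frames = {}
    for name in _TABLES:
        df = pd.read_csv(indir / f"{name}.tsv", sep="\t", dtype={"icd10": str, "code": str})
        for col in _DATE_COLS.get(name, []):
            df[col] = pd.to_datetime(df[col])
        if name == "hierarchy":
            df["parent"] = df.get("parent", pd.Series(dtype=str)).fillna("")
        frames[name] = df
    payload = json.loads((indir / "truth_manifest.json").read_text())
    manifest = TruthManifest(
        status=pd.DataFrame(payload["status"]),
        gene_effects=pd.DataFrame(payload["gene_effects"]),
    )
    return Biobank(**frames), manifest
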