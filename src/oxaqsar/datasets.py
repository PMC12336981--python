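"""Embedded study dataset and elementary descriptor transforms.

The study data — a panel of 33 dihydropteridone–oxadiazole MCF-7 inhibitors
with 17 computed molecular descriptors, a 31-row modeling table carrying the
six model descriptors (S, Tor, MP, NRB, repul, eta) and observed pIC50, a
6-compound external test set, five designed candidate molecules, and their
drug-likeness property rows — ships with the package as plain CSV fixtures.
Every value is stored at its source precision and validated against a sha256
manifest plus a set of structural invariants at load time.

Two numbering systems coexist: the descriptor panel numbers all 33 compounds,
while the modeling table is keyed by its own row order (31 rows; two panel
compounds were excluded from modeling and the row numbering does not align
with the panel's). No join between the two is defined or attempted.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

#: Descriptor columns of the activity models, in canonical order.
MODEL_TERMS = ["S", "Tor", "MP", "NRB", "repul", "eta"]

#: Column order of the modeling-record CSV dialect.
CSV_COLUMNS = ["compound_id", "S", "Tor", "MP", "NRB", "repul", "eta",
               "pIC50_obs", "split"]


class FixtureIntegrityError(RuntimeError):
    """Raised when an embedded fixture fails its checksum or an invariant."""


def ic50_to_pic50(ic50):
    """Convert a micromolar IC50 to pIC50 = 6 - log10(IC50).

    Parameters
    ----------
    ic50 : float or array-like
        Half-maximal inhibitory concentration in µM; must be > 0.
    """
    ic50 = np.asarray(ic50, dtype=float)
    if np.any(ic50 <= 0):
        raise ValueError("IC50 must be strictly positive")
    out = 6.0 - np.log10(ic50)
    return float(out) if out.ndim == 0 else out


def hardness_from_orbitals(e_homo, e_lumo):
    """Global hardness eta = (E_LUMO - E_HOMO) / 2, in Hartree.

    The frontier-orbital half-gap; requires E_LUMO > E_HOMO.
    """
    e_homo = np.asarray(e_homo, dtype=float)
    e_lumo = np.asarray(e_lumo, dtype=float)
    if np.any(e_lumo <= e_homo):
        raise ValueError("E_LUMO must exceed E_HOMO (non-positive gap)")
    out = (e_lumo - e_homo) / 2.0
    return float(out) if out.ndim == 0 else out


@dataclass
class StudyDataset:
    """The full study data, one attribute per source table.

    Attributes
    ----------
    modeling : DataFrame
        31 modeling records: the six model descriptors, observed pIC50 and
        a train/test split label, in modeling-table row order.
    panel : DataFrame
        33-compound extended descriptor panel (includes frontier-orbital
        energies and the unused descriptors).
    published_predictions : DataFrame
        The source MLR/MNLR predictions and residuals for the 31 modeling
        records (reference values, never recomputed).
    test_pairs : DataFrame
        Observed / published-MLR-predicted activity pairs for the 6-compound
        external test set.
    candidates : DataFrame
        The five designed compounds M1..M5: model descriptors plus the
        published predicted activity.
    candidate_properties : DataFrame
        Physicochemical properties of the candidates for drug-likeness
        screening, plus pass-through annotations (synthetic accessibility,
        AMES) computed by external tools.
    metadata : dict
        Fixture provenance notes (exclusions, numbering caveats).
    """

    modeling: pd.DataFrame
    panel: pd.DataFrame
    published_predictions: pd.DataFrame
    test_pairs: pd.DataFrame
    candidates: pd.DataFrame
    candidate_properties: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def training(self) -> pd.DataFrame:
        """The 25 training records."""
        return self.modeling[self.modeling["split"] == "train"].reset_index(drop=True)

    def test(self) -> pd.DataFrame:
        """The 6 held-out test records."""
        return self.modeling[self.modeling["split"] == "test"].reset_index(drop=True)

    @property
    def max_observed_activity(self) -> float:
        """Highest observed pIC50 among the modeling compounds (baseline
        against which candidate improvements are measured)."""
        return float(self.modeling["pIC50_obs"].max())


def _data_dir():
    return resources.files("oxaqsar") / "data"


def _read(name: str) -> pd.DataFrame:
    with resources.as_file(_data_dir() / name) as path:
        return pd.read_csv(path)


def _verify_checksums() -> dict:
    with resources.as_file(_data_dir() / "manifest.json") as path:
        manifest = json.loads(Path(path).read_text())
    for name, expected in manifest["files"].items():
        with resources.as_file(_data_dir() / name) as path:
            digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        if digest != expected:
            raise FixtureIntegrityError(
                f"fixture {name!r}: checksum mismatch (corrupted packaging?)")
    return manifest


def _validate(ds: StudyDataset) -> None:
    m = ds.modeling
    if len(m) != 31:
        raise FixtureIntegrityError("modeling table must have 31 rows")
    n_train = int((m["split"] == "train").sum())
    n_test = int((m["split"] == "test").sum())
    if (n_train, n_test) != (25, 6):
        raise FixtureIntegrityError(f"split must be 25 train / 6 test, got {n_train}/{n_test}")
    test_ids = set(m.loc[m["split"] == "test", "compound_id"].astype(str))
    if test_ids != {"3", "4", "12", "21", "24", "29"}:
        raise FixtureIntegrityError(f"unexpected test-set compounds: {sorted(test_ids)}")
    if not ((m["NRB"] >= 0) & (m["NRB"] == m["NRB"].astype(int))).all():
        raise FixtureIntegrityError("NRB must be non-negative integers")
    for col in ("S", "repul", "eta"):
        if not (m[col] > 0).all():
            raise FixtureIntegrityError(f"{col} must be strictly positive")
    if m["pIC50_obs"].isna().any():
        raise FixtureIntegrityError("observed activity missing for a modeling record")

    p = ds.panel
    if len(p) != 33:
        raise FixtureIntegrityError("descriptor panel must have 33 rows")
    if not (p["E_HOMO"] < p["E_LUMO"]).all():
        raise FixtureIntegrityError("panel: E_HOMO must lie below E_LUMO")
    eta_gap = np.abs(p["eta"] - (p["E_LUMO"] - p["E_HOMO"]) / 2.0)
    if not (eta_gap <= 1e-4).all():
        raise FixtureIntegrityError("panel: stored hardness inconsistent with orbital gap")

    # Published predictions must be internally consistent with observations.
    pp = ds.published_predictions
    resid_gap = np.abs((m["pIC50_obs"].to_numpy() - pp["mlr_pred"].to_numpy())
                       - pp["mlr_resid"].to_numpy())
    if not (resid_gap <= 0.01).all():
        raise FixtureIntegrityError("published MLR residuals inconsistent with observations")

    c = ds.candidates
    if list(c["compound_id"]) != ["M1", "M2", "M3", "M4", "M5"]:
        raise FixtureIntegrityError("candidates must be M1..M5 in order")


def load_study_dataset() -> StudyDataset:
    """Load and validate the embedded study dataset.

    Verifies the sha256 manifest and the structural invariants of every
    table; raises :class:`FixtureIntegrityError` on any mismatch.
    """
    manifest = _verify_checksums()
    ds = StudyDataset(
        modeling=_read("modeling_records.csv").assign(
            compound_id=lambda d: d["compound_id"].astype(str)),
        panel=_read("descriptor_panel.csv"),
        published_predictions=_read("published_predictions.csv").assign(
            compound_id=lambda d: d["compound_id"].astype(str)),
        test_pairs=_read("test_pairs.csv").assign(
            compound_id=lambda d: d["compound_id"].astype(str)),
        candidates=_read("candidates.csv"),
        candidate_properties=_read("candidate_properties.csv"),
        metadata={"notes": manifest.get("notes", "")},
    )
    _validate(ds)
    return ds


def write_records_csv(records: pd.DataFrame, path) -> None:
    """Write modeling-style records in the package CSV dialect
    (UTF-8, comma-separated, header ``compound_id,S,Tor,MP,NRB,repul,eta,
    pIC50_obs,split``)."""
    records.loc[:, CSV_COLUMNS].to_csv(path, index=False, encoding="utf-8")


def read_records_csv(path) -> pd.DataFrame:
    """Read records written by :func:`write_records_csv`."""
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"records CSV missing columns: {missing}")
    return df.assign(compound_id=df["compound_id"].astype(str))[CSV_COLUMNS]
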