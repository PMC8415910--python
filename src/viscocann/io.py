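"""Tabular readers/writers and the in-memory dataset container.

Two plain CSV dialects (UTF-8, comma separator, period decimal):

* mechanics table -- columns ``specimen_id, protocol, time_s, stretch,
  nominal_stress_kPa``; time strictly increasing within each
  (specimen, protocol) group; stretch in (0, 2).
* composition table -- columns ``specimen_id, region`` followed by the 11
  feature columns in the fixed order (ng per mg total protein), one row
  per specimen.

Validation errors name the file, row and column involved; missing values
are flagged, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import FEATURES, REGIONS, CompositionVector

__all__ = [
    "PROTOCOL_KINDS",
    "SpecimenData",
    "read_mechanics",
    "write_mechanics",
    "read_composition",
    "write_composition",
    "load_dataset",
    "write_dataset",
]

PROTOCOL_KINDS = ("cyclic", "relax_compression", "relax_tension")

MECHANICS_COLUMNS = ["specimen_id", "protocol", "time_s", "stretch", "nominal_stress_kPa"]

#: Accepted alternative spellings for composition feature headers, as they
#: appear in assay reports ("Col I", "LA" for laminin, ...).
FEATURE_ALIASES = {
    "Col I": "ColI",
    "Col IV": "ColIV",
    "Col VI": "ColVI",
    "Col_I": "ColI",
    "Col_IV": "ColIV",
    "Col_VI": "ColVI",
    "LA": "LAM",
    "Lum": "LUM",
    "IBA1": "Iba1",
}


@dataclass
class SpecimenData:
    """One specimen: composition plus per-protocol (t, stretch, stress) series."""

    specimen_id: str
    composition: CompositionVector
    protocols: dict  # kind -> (time_s, stretch, stress_kPa) arrays

    @property
    def region(self) -> str:
        return self.composition.region

    def cyclic(self):
        return self.protocols["cyclic"]


def read_mechanics(path) -> pd.DataFrame:
    """Read and validate a mechanics table."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in MECHANICS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mechanics column(s) {missing}")
    if df[MECHANICS_COLUMNS].isna().any().any():
        col = df[MECHANICS_COLUMNS].isna().any().idxmax()
        row = int(df[col].isna().idxmax())
        raise ValueError(f"{path}: missing value in column {col!r} at row {row}")
    bad = ~df["protocol"].isin(PROTOCOL_KINDS)
    if bad.any():
        row = int(bad.idxmax())
        raise ValueError(
            f"{path}: unknown protocol {df.loc[row, 'protocol']!r} at row {row}; "
            f"allowed: {PROTOCOL_KINDS}"
        )
    out_of_range = ~((df["stretch"] > 0.0) & (df["stretch"] < 2.0))
    if out_of_range.any():
        row = int(out_of_range.idxmax())
        raise ValueError(
            f"{path}: stretch {df.loc[row, 'stretch']!r} outside (0, 2) at row {row}"
        )
    for (sid, protocol), grp in df.groupby(["specimen_id", "protocol"], sort=False):
        t = grp["time_s"].to_numpy()
        dt = np.diff(t)
        if np.any(dt <= 0.0):
            k = int(np.argmax(dt <= 0.0)) + 1
            row = int(grp.index[k])
            raise ValueError(
                f"{path}: non-increasing time_s at row {row} "
                f"(specimen {sid!r}, protocol {protocol!r})"
            )
    return df.reset_index(drop=True)


def write_mechanics(path, df: pd.DataFrame) -> None:
    df[MECHANICS_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def read_composition(path) -> pd.DataFrame:
    """Read and validate a composition table (11 features, fixed order)."""
    path = Path(path)
    df = pd.read_csv(path)
    df = df.rename(columns=FEATURE_ALIASES)
    for col in ("specimen_id", "region"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    missing = [f for f in FEATURES if f not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing composition feature column(s) {missing}")
    bad_region = ~df["region"].isin(REGIONS)
    if bad_region.any():
        row = int(bad_region.idxmax())
        raise ValueError(
            f"{path}: unknown region {df.loc[row, 'region']!r} at row {row}; allowed: {REGIONS}"
        )
    if df["specimen_id"].duplicated().any():
        dup = df.loc[df["specimen_id"].duplicated(), "specimen_id"].iloc[0]
        raise ValueError(f"{path}: duplicated specimen_id {dup!r}")
    for f in FEATURES:
        if df[f].isna().any():
            row = int(df[f].isna().idxmax())
            raise ValueError(f"{path}: missing value for feature {f!r} at row {row}")
        neg = df[f] < 0.0
        if neg.any():
            row = int(neg.idxmax())
            raise ValueError(
                f"{path}: negative concentration {df.loc[row, f]!r} for {f!r} at row {row}"
            )
    return df[["specimen_id", "region", *FEATURES]].reset_index(drop=True)


def write_composition(path, df: pd.DataFrame) -> None:
    df[["specimen_id", "region", *FEATURES]].to_csv(path, index=False, float_format="%.17g")


def specimens_to_tables(specimens) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten SpecimenData objects into (mechanics, composition) frames."""
    mech_rows = []
    comp_rows = []
    for sp in specimens:
        for kind, (t, lam, P) in sp.protocols.items():
            mech_rows.append(
                pd.DataFrame(
                    {
                        "specimen_id": sp.specimen_id,
                        "protocol": kind,
                        "time_s": t,
                        "stretch": lam,
                        "nominal_stress_kPa": P,
                    }
                )
            )
        comp_rows.append(
            {"specimen_id": sp.specimen_id, "region": sp.region, **sp.composition.as_dict()}
        )
    return pd.concat(mech_rows, ignore_index=True), pd.DataFrame(comp_rows)


def load_dataset(mechanics_path, composition_path) -> list[SpecimenData]:
    """Assemble validated SpecimenData objects from the two tables."""
    mech = read_mechanics(mechanics_path)
    comp = read_composition(composition_path)
    mech_ids = set(mech["specimen_id"])
    comp_ids = set(comp["specimen_id"])
    if mech_ids != comp_ids:
        raise ValueError(
            f"specimen_id mismatch between tables: only in mechanics {sorted(mech_ids - comp_ids)}, "
            f"only in composition {sorted(comp_ids - mech_ids)}"
        )
    specimens = []
    for _, row in comp.iterrows():
        cv = CompositionVector(
            values=row[list(FEATURES)].to_numpy(dtype=float), region=row["region"]
        )
        protocols = {}
        sub = mech[mech["specimen_id"] == row["specimen_id"]]
        for kind, grp in sub.groupby("protocol", sort=False):
            protocols[kind] = (
                grp["time_s"].to_numpy(),
                grp["stretch"].to_numpy(),
                grp["nominal_stress_kPa"].to_numpy(),
            )
        specimens.append(
            SpecimenData(specimen_id=row["specimen_id"], composition=cv, protocols=protocols)
        )
    return specimens


def write_dataset(outdir, specimens) -> tuple[Path, Path]:
    """Write mechanics.csv + composition.csv under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mech, comp = specimens_to_tables(specimens)
    mech_path = outdir / "mechanics.csv"
    comp_path = outdir / "composition.csv"
    write_mechanics(mech_path, mech)
    write_composition(comp_path, comp)
    return mech_path, comp_path
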