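"""CSV readers/writers for the pipeline's tabular interchange formats.

All files are plain CSV with a header row; missing values are empty fields.
Schemas (required columns):

- ``trees.csv``     — tree_id, provenance, block, then trait columns; for the
  growth stage: dbh_cm, height_m, survey_date (ISO dates, one row per survey)
- ``vessels.csv``   — branch_id, a_um, b_um (major/minor radii, μm)
- ``branches.csv``  — branch_id, a_cross_mm2 and/or a_xylem_mm2,
  branch_age_yr, leaf_area_m2 (optional)
- ``plc.csv``       — branch_id, pressure_mpa (negative), plc or conductance
- ``climate.csv``   — provenance, month (1–12), tmean_c, prec_mm, gai (optional)

Pressures must be negative (tensions) unless the ``tension_positive`` dialect
flag is set, in which case positive magnitudes are negated on read.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .anatomy import CrossSectionSample, VesselRecord
from .climate import MonthlyClimate
from .vulnerability import PLCSeries, plc_from_conductance

__all__ = [
    "SchemaError",
    "read_vessels",
    "read_branches",
    "read_cross_sections",
    "read_plc",
    "read_climate",
]


class SchemaError(ValueError):
    """A tabular input violates its documented schema."""


def _require(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_vessels(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["branch_id", "a_um", "b_um"], path)
    bad = df.index[(df["a_um"] <= 0) | (df["b_um"] <= 0)]
    if len(bad):
        raise SchemaError(f"{path}: non-positive radius at row(s) {list(bad[:5])}")
    return df


def read_branches(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["branch_id"], path)
    if "a_cross_mm2" not in df.columns and "a_xylem_mm2" not in df.columns:
        raise SchemaError(f"{path}: need a_cross_mm2 or a_xylem_mm2")
    return df


def read_cross_sections(vessels_path, branches_path) -> list[CrossSectionSample]:
    """Join vessels with branch metadata into per-branch samples."""
    vessels = read_vessels(vessels_path)
    branches = read_branches(branches_path).set_index("branch_id")
    samples = []
    for branch_id, grp in vessels.groupby("branch_id", sort=True):
        if branch_id not in branches.index:
            raise SchemaError(
                f"{vessels_path}: branch {branch_id!r} missing from {branches_path}"
            )
        meta = branches.loc[branch_id]

        def opt(col, cast=float):
            v = meta.get(col)
            return None if v is None or pd.isna(v) else cast(v)

        samples.append(
            CrossSectionSample(
                branch_id=str(branch_id),
                vessels=[
                    VesselRecord(a=row.a_um, b=row.b_um)
                    for row in grp.itertuples()
                ],
                a_cross_mm2=opt("a_cross_mm2"),
                a_xylem_mm2=opt("a_xylem_mm2"),
                branch_age_yr=opt("branch_age_yr", int),
                leaf_area_m2=opt("leaf_area_m2"),
            )
        )
    return samples


def read_plc(path, tension_positive: bool = False) -> list[PLCSeries]:
    """Per-branch PLC series; conductances are converted via the branch max."""
    df = pd.read_csv(path)
    _require(df, ["branch_id", "pressure_mpa"], path)
    if "plc" not in df.columns and "conductance" not in df.columns:
        raise SchemaError(f"{path}: need a plc or conductance column")
    if tension_positive:
        df = df.assign(pressure_mpa=-df["pressure_mpa"].abs())
    elif (df["pressure_mpa"] > 0).any():
        raise SchemaError(
            f"{path}: positive pressures found; tensions must be negative "
            "(or pass tension_positive=True)"
        )
    series = []
    for branch_id, grp in df.groupby("branch_id", sort=True):
        grp = grp.sort_values("pressure_mpa", ascending=False)
        if "plc" in grp.columns and grp["plc"].notna().all():
            plc = grp["plc"].to_numpy(float)
        else:
            k = grp["conductance"].to_numpy(float)
            k_max = k.max()
            plc = np.array([plc_from_conductance(ki, k_max) for ki in k])
        series.append(
            PLCSeries(
                branch_id=str(branch_id),
                pressures_mpa=grp["pressure_mpa"].to_numpy(float),
                plc=plc,
            )
        )
    return series


def read_climate(path) -> list[MonthlyClimate]:
    df = pd.read_csv(path)
    _require(df, ["provenance", "month", "tmean_c", "prec_mm"], path)
    out = []
    for prov, grp in df.groupby("provenance", sort=True):
        grp = grp.sort_values("month")
        if list(grp["month"]) != list(range(1, 13)):
            raise SchemaError(f"{path}: provenance {prov!r} lacks months 1..12")
        gai = None
        if "gai" in grp.columns and grp["gai"].notna().any():
            gai = float(grp["gai"].iloc[0])
        out.append(
            MonthlyClimate(
                provenance=str(prov),
                tmean_c=grp["tmean_c"].to_numpy(float),
                prec_mm=grp["prec_mm"].to_numpy(float),
                gai=gai,
            )
        )
    return out


def write_csv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
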