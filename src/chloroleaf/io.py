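"""Delimited-text table schemas shared by the library and the CLI.

All on-disk formats are plain delimited text (comma by default, UTF-8,
header mandatory), read and written through pandas:

* readings table: ``sample_id, replicate, r_raw, g_raw, b_raw, c_raw``
* feature table: ``sample_id`` + the 20 canonical feature columns
* calibration table: readings columns + ``cla_mg_g, clb_mg_g,
  tcl_mg_g, crop`` (optional ``spad``)
* assay table: ``sample_id, a645, a663, leaf_mass_g`` (optional
  ``extract_volume_ml``)
* estimates table: ``sample_id, cla_mg_g, clb_mg_g, tcl_mg_g, status``
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .calibration import CalibrationDataset, CalibrationRow
from .colorspace import FEATURE_NAMES, SensorReading, average_replicates, extract_features
from .errors import SchemaError
from .models import ChlorophyllEstimate
from .reference_assay import (
    AbsorbanceRecord,
    ChlorophyllReference,
    reference_from_absorbances,
)

__all__ = [
    "read_readings_table",
    "readings_by_sample",
    "write_feature_table",
    "read_calibration_table",
    "read_assay_table",
    "assay_to_reference_table",
    "write_estimates_table",
    "validate_reference_contents",
]

READINGS_COLUMNS = ("sample_id", "replicate", "r_raw", "g_raw", "b_raw", "c_raw")
CALIBRATION_COLUMNS = READINGS_COLUMNS + ("cla_mg_g", "clb_mg_g", "tcl_mg_g", "crop")
ASSAY_COLUMNS = ("sample_id", "a645", "a663", "leaf_mass_g")


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {missing}")


def read_readings_table(path: str | Path, sep: str = ",") -> pd.DataFrame:
    """Read and validate a readings table."""
    df = pd.read_csv(path, sep=sep)
    _require_columns(df, READINGS_COLUMNS, "readings table")
    return df


def readings_by_sample(df: pd.DataFrame) -> dict[str, list[SensorReading]]:
    """Group a readings table into per-sample replicate lists.

    Preserves first-appearance order of sample ids.
    """
    out: dict[str, list[SensorReading]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["sample_id"]), []).append(
            SensorReading(
                r_raw=float(row["r_raw"]),
                g_raw=float(row["g_raw"]),
                b_raw=float(row["b_raw"]),
                c_raw=float(row["c_raw"]),
            )
        )
    return out


def write_feature_table(
    features: Mapping[str, "object"], path: str | Path, sep: str = ","
) -> None:
    """Write sample_id + the 20 canonical feature columns, fixed order."""
    records = []
    for sample_id, feats in features.items():
        rec = {"sample_id": sample_id}
        rec.update(feats.as_dict())  # type: ignore[attr-defined]
        records.append(rec)
    pd.DataFrame(records, columns=["sample_id", *FEATURE_NAMES]).to_csv(
        path, sep=sep, index=False
    )


def read_calibration_table(path: str | Path, sep: str = ",") -> CalibrationDataset:
    """Read a calibration table: replicates are averaged per sample, then
    features extracted once from the mean reading."""
    df = pd.read_csv(path, sep=sep)
    _require_columns(df, CALIBRATION_COLUMNS, "calibration table")
    rows = []
    for sample_id, group in df.groupby("sample_id", sort=False):
        readings = [
            SensorReading(
                float(r["r_raw"]), float(r["g_raw"]), float(r["b_raw"]), float(r["c_raw"])
            )
            for _, r in group.iterrows()
        ]
        mean_reading = average_replicates(readings)
        first = group.iloc[0]
        rows.append(
            CalibrationRow(
                sample_id=str(sample_id),
                features=extract_features(mean_reading),
                cla=float(first["cla_mg_g"]),
                clb=float(first["clb_mg_g"]),
                tcl=float(first["tcl_mg_g"]),
                crop=str(first["crop"]),
                spad=float(first["spad"]) if "spad" in group.columns else None,
            )
        )
    return CalibrationDataset(tuple(rows))


def read_assay_table(path: str | Path, sep: str = ",") -> dict[str, AbsorbanceRecord]:
    """Read a spectrophotometric assay table into per-sample records."""
    df = pd.read_csv(path, sep=sep)
    _require_columns(df, ASSAY_COLUMNS, "assay table")
    out = {}
    for _, row in df.iterrows():
        volume = (
            float(row["extract_volume_ml"]) if "extract_volume_ml" in df.columns else 5.0
        )
        out[str(row["sample_id"])] = AbsorbanceRecord(
            a645=float(row["a645"]),
            a663=float(row["a663"]),
            leaf_mass=float(row["leaf_mass_g"]),
            extract_volume=volume,
        )
    return out


def assay_to_reference_table(
    records: Mapping[str, AbsorbanceRecord], path: str | Path, sep: str = ","
) -> pd.DataFrame:
    """Compute reference contents for each assay record and write a
    reference-contents table consumable by calibration."""
    rows = []
    for sample_id, record in records.items():
        ref = reference_from_absorbances(record)
        rows.append(
            {
                "sample_id": sample_id,
                "cla_mg_g": ref.cla,
                "clb_mg_g": ref.clb,
                "tcl_mg_g": ref.tcl,
            }
        )
    df = pd.DataFrame(rows, columns=["sample_id", "cla_mg_g", "clb_mg_g", "tcl_mg_g"])
    df.to_csv(path, sep=sep, index=False)
    return df


def validate_reference_contents(
    df: pd.DataFrame, tol: float = 0.02
) -> None:
    """Consistency check on a reference-contents table: the total must
    equal chlorophyll-a + chlorophyll-b within ``tol`` mg/g per row.

    Catches unit mix-ups and column swaps before contents enter
    calibration.

    Raises
    ------
    SchemaError
        Naming the first offending sample.
    """
    _require_columns(df, ("cla_mg_g", "clb_mg_g", "tcl_mg_g"), "reference table")
    gap = (df["tcl_mg_g"] - df["cla_mg_g"] - df["clb_mg_g"]).abs()
    bad = gap > tol
    if bad.any():
        i = int(bad.idxmax())
        sid = df["sample_id"].iloc[i] if "sample_id" in df.columns else i
        raise SchemaError(
            f"reference contents inconsistent for sample {sid!r}: "
            f"|tcl - (cla + clb)| = {gap.iloc[i]:.4f} mg/g > {tol}"
        )


def write_estimates_table(
    estimates: Mapping[str, ChlorophyllEstimate], path: str | Path, sep: str = ","
) -> None:
    """Write per-sample estimates: contents (mg/g) + status flag."""
    rows = [
        {
            "sample_id": sample_id,
            "cla_mg_g": est.cla,
            "clb_mg_g": est.clb,
            "tcl_mg_g": est.tcl,
            "status": est.status,
        }
        for sample_id, est in estimates.items()
    ]
    pd.DataFrame(
        rows, columns=["sample_id", "cla_mg_g", "clb_mg_g", "tcl_mg_g", "status"]
    ).to_csv(path, sep=sep, index=False)
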