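"""Tabular IO: the flat field-table CSV and result serializations.

The field table is the package's interchange format: one row per
field-year with fixed, schema-defined column order, UTF-8, comma
delimiter, ``.`` decimal point, and floats at 6 significant digits —
so identical runs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .aggregation import ScoreReport
from .errors import InputError
from .types import (
    FieldContext,
    FieldYearRecord,
    GroundwaterClass,
    LandUse,
    ManagementRecord,
    SoilProfile,
    SoilType,
    VSARating,
    VSARecord,
    PROPERTY_NAMES,
    VSA_ITEMS,
)

__all__ = [
    "FIELD_TABLE_COLUMNS",
    "records_to_frame",
    "frame_to_records",
    "write_field_table",
    "read_field_table",
    "write_score_reports",
]

MANDATORY_COLUMNS = (
    "field_id", "year_age", "soil_type", "groundwater_class", "land_use",
)
_VSA_COLUMNS = tuple(f"vsa_{item}" for item in VSA_ITEMS)

#: Canonical column order of the field table.
FIELD_TABLE_COLUMNS: tuple[str, ...] = (
    MANDATORY_COLUMNS
    + ("crop_code",)
    + PROPERTY_NAMES
    + ("management_score",)
    + _VSA_COLUMNS
)

FLOAT_FORMAT = "%.6g"


def records_to_frame(records: Sequence[FieldYearRecord]) -> pd.DataFrame:
    """Flatten records into the canonical field table."""
    rows = []
    for rec in records:
        row: dict[str, Any] = {
            "field_id": rec.field_id,
            "year_age": rec.year_age,
            "soil_type": rec.context.soil_type.value,
            "groundwater_class": rec.context.groundwater_class.value,
            "land_use": rec.context.land_use.value,
            "crop_code": rec.context.crop_code,
        }
        for name in PROPERTY_NAMES:
            row[name] = getattr(rec.profile, name)
        row["management_score"] = (
            rec.management.score if rec.management is not None else None
        )
        for item in VSA_ITEMS:
            row[f"vsa_{item}"] = (
                getattr(rec.vsa, item).value if rec.vsa is not None else None
            )
        rows.append(row)
    return pd.DataFrame(rows, columns=list(FIELD_TABLE_COLUMNS))


def _cell(row: pd.Series, name: str) -> Any:
    v = row.get(name)
    if v is None or (isinstance(v, float) and np.isnan(v)) or v is pd.NA:
        return None
    return v


def _row_to_record(row: pd.Series) -> FieldYearRecord:
    profile = SoilProfile(**{
        name: (None if _cell(row, name) is None else float(row[name]))
        for name in PROPERTY_NAMES
    })
    context = FieldContext(
        soil_type=SoilType(str(row["soil_type"])),
        groundwater_class=GroundwaterClass(str(row["groundwater_class"])),
        land_use=LandUse(str(row["land_use"])),
        crop_code=str(_cell(row, "crop_code") or ""),
    )
    mgmt_score = _cell(row, "management_score")
    management = (
        ManagementRecord(score=float(mgmt_score)) if mgmt_score is not None else None
    )
    vsa_values = {item: _cell(row, f"vsa_{item}") for item in VSA_ITEMS}
    present = [v for v in vsa_values.values() if v is not None]
    if present and len(present) < len(VSA_ITEMS):
        missing = sorted(k for k, v in vsa_values.items() if v is None)
        raise InputError(f"incomplete VSA record: missing {missing}")
    vsa = (
        VSARecord(**{k: VSARating(str(v)) for k, v in vsa_values.items()})
        if present
        else None
    )
    rec = FieldYearRecord(
        field_id=str(row["field_id"]),
        year_age=int(row["year_age"]),
        profile=profile,
        context=context,
        management=management,
        vsa=vsa,
    )
    rec.validate()
    return rec


def frame_to_records(
    frame: pd.DataFrame, *, strict: bool = True
) -> tuple[list[FieldYearRecord], list[str]]:
    """Convert a field table to validated records.

    Returns ``(records, problems)``; with ``strict=True`` the first
    invalid row raises, otherwise invalid rows are skipped and reported
    with their row numbers.
    """
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise InputError(f"field table missing mandatory columns: {missing}")
    unknown = [c for c in frame.columns if c not in FIELD_TABLE_COLUMNS]
    problems: list[str] = []
    if unknown:
        problems.append(f"ignoring unknown columns: {unknown}")
    records: list[FieldYearRecord] = []
    for i, (_, row) in enumerate(frame.iterrows()):
        try:
            records.append(_row_to_record(row))
        except (InputError, ValueError) as exc:
            msg = f"row {i + 2}: {exc}"  # +2: header line + 1-based
            if strict:
                raise InputError(msg) from None
            problems.append(msg)
    return records, problems


def write_field_table(records: Sequence[FieldYearRecord], path: str | Path) -> None:
    frame = records_to_frame(records)
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_field_table(
    path: str | Path, *, strict: bool = True
) -> tuple[list[FieldYearRecord], list[str]]:
    """Read and validate a field-table CSV; see :func:`frame_to_records`."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    frame = pd.read_csv(path, dtype={"field_id": str, "crop_code": str})
    return frame_to_records(frame, strict=strict)


def write_score_reports(
    reports: Sequence[ScoreReport],
    csv_path: str | Path | None = None,
    json_path: str | Path | None = None,
) -> None:
    """Serialize score reports: flat CSV (one row per field) and/or
    nested JSON (per-year and per-category detail plus weights)."""
    if csv_path is not None:
        frame = pd.DataFrame([r.to_flat_row() for r in reports])
        frame.to_csv(csv_path, index=False, float_format=FLOAT_FORMAT)
    if json_path is not None:
        payload = [r.to_dict() for r in reports]
        with open(json_path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
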