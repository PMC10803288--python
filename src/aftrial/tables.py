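"""Patient-table serialization.

The on-disk dialect is versioned, comma-separated UTF-8 with an explicit
``NA`` token for missing values and a ``#``-prefixed header comment naming
the schema version. The delta-QTcF series is flattened onto fixed-grid
columns ``dqtcf_<minutes>``. Round-trips are lossless at float precision.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .cohort import PatientRecord, QTCF_GRID_MIN

__all__ = ["SCHEMA_VERSION", "records_to_frame", "frame_to_records",
           "write_cohort", "read_cohort", "REQUIRED_COLUMNS"]

SCHEMA_VERSION = "aftrial-patient-table v1"
NA = "NA"

_QTCF_COLS = [f"dqtcf_{int(t)}" for t in QTCF_GRID_MIN]

_BOOL_COLS = [
    "infused", "flutter_at_randomization", "dccv_within_90min", "converted",
    "recurrence_1min", "relapse_5min", "dccv_performed", "dccv_success",
    "sinus_3h", "sinus_24h", "sinus_30d", "male",
]
_FLOAT_COLS = [
    "dose", "conversion_time_min", "age", "weight_kg", "af_duration_h",
    "baseline_qtcf_ms", *_QTCF_COLS,
]

REQUIRED_COLUMNS = ["id", "arm", "infused", "flutter_at_randomization", "dccv_within_90min"]

COLUMNS = (
    ["id", "arm", "dose", "infused", "flutter_at_randomization", "dccv_within_90min",
     "converted", "conversion_time_min", "recurrence_1min", "relapse_5min",
     "dccv_performed", "dccv_success", "sinus_3h", "sinus_24h", "sinus_30d",
     "age", "male", "weight_kg", "af_duration_h", "baseline_qtcf_ms"]
    + _QTCF_COLS
)


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "id": r.id, "arm": r.arm, "dose": r.dose, "infused": r.infused,
            "flutter_at_randomization": r.flutter_at_randomization,
            "dccv_within_90min": r.dccv_within_90min, "converted": r.converted,
            "conversion_time_min": r.conversion_time_min,
            "recurrence_1min": r.recurrence_1min, "relapse_5min": r.relapse_5min,
            "dccv_performed": r.dccv_performed, "dccv_success": r.dccv_success,
            "sinus_3h": r.sinus_3h, "sinus_24h": r.sinus_24h, "sinus_30d": r.sinus_30d,
            "age": r.age, "male": r.male, "weight_kg": r.weight_kg,
            "af_duration_h": r.af_duration_h, "baseline_qtcf_ms": r.baseline_qtcf_ms,
        }
        series = r.dqtcf_ms if r.dqtcf_ms is not None else [None] * len(QTCF_GRID_MIN)
        for col, value in zip(_QTCF_COLS, series):
            row[col] = value
        rows.append(row)
    return pd.DataFrame(rows, columns=COLUMNS)


def _opt_bool(value) -> Optional[bool]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value is pd.NA:
        return None
    if isinstance(value, (bool,)):
        return value
    s = str(value).strip()
    if s in ("True", "true", "1", "1.0"):
        return True
    if s in ("False", "false", "0", "0.0"):
        return False
    if s in (NA, "", "nan", "None"):
        return None
    raise ValueError(f"cannot parse boolean value {value!r}")


def _opt_float(value) -> Optional[float]:
    if value is None or value is pd.NA:
        return None
    try:
        f = float(value)
    except (TypeError, ValueError):
        if str(value).strip() in (NA, "", "None"):
            return None
        raise
    return None if pd.isna(f) else f


def frame_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    from .survival import SchemaError

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"patient table is missing required column(s): {missing}")
    records = []
    for _, row in df.iterrows():
        qtcf = None
        if all(c in df.columns for c in _QTCF_COLS):
            vals = [_opt_float(row[c]) for c in _QTCF_COLS]
            if all(v is not None for v in vals):
                qtcf = tuple(vals)
        records.append(PatientRecord(
            id=int(row["id"]),
            arm=str(row["arm"]),
            dose=_opt_float(row.get("dose")),
            infused=bool(_opt_bool(row["infused"])),
            flutter_at_randomization=bool(_opt_bool(row["flutter_at_randomization"])),
            dccv_within_90min=bool(_opt_bool(row["dccv_within_90min"])),
            converted=_opt_bool(row.get("converted")),
            conversion_time_min=_opt_float(row.get("conversion_time_min")),
            recurrence_1min=_opt_bool(row.get("recurrence_1min")),
            relapse_5min=_opt_bool(row.get("relapse_5min")),
            dccv_performed=_opt_bool(row.get("dccv_performed")),
            dccv_success=_opt_bool(row.get("dccv_success")),
            sinus_3h=_opt_bool(row.get("sinus_3h")),
            sinus_24h=_opt_bool(row.get("sinus_24h")),
            sinus_30d=_opt_bool(row.get("sinus_30d")),
            age=_opt_float(row.get("age")),
            male=_opt_bool(row.get("male")),
            weight_kg=_opt_float(row.get("weight_kg")),
            af_duration_h=_opt_float(row.get("af_duration_h")),
            baseline_qtcf_ms=_opt_float(row.get("baseline_qtcf_ms")),
            dqtcf_ms=qtcf,
        ))
    return records


def write_cohort(records: Sequence[PatientRecord], path, force: bool = False) -> None:
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True (--force) to overwrite")
    df = records_to_frame(records)
    buf = io.StringIO()
    buf.write(f"# {SCHEMA_VERSION}\n")
    df.to_csv(buf, index=False, na_rep=NA)
    path.write_text(buf.getvalue(), encoding="utf-8")


def read_cohort(path) -> list[PatientRecord]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"patient table not found: {path}")
    df = pd.read_csv(path, comment="#", na_values=[NA], keep_default_na=True,
                     encoding="utf-8")
    return frame_to_records(df)
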