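"""Tidy CSV dialects for wells, standards, resistance records and reports.

All files are UTF-8 CSV with a header row and "." as the decimal
separator. An em dash ("—") or empty field marks a missing value, the
convention transport reports use for absent assay arms; readers map both
to NaN and writers render NaN back as the em dash. Schema violations
raise :class:`SchemaError` naming the file, row and column.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .transport import TEERRecord, WellTimeSeries, teer_record

__all__ = [
    "SchemaError",
    "MISSING",
    "read_wells_csv",
    "write_wells_csv",
    "read_standards_csv",
    "read_resistance_csv",
    "write_frame",
    "read_frame",
]

MISSING = "—"
_NA_VALUES = [MISSING, "", "NA", "NaN"]

WELLS_COLUMNS = ["well_id", "condition", "compound", "direction",
                 "c0_ug_per_ml", "vr_ml", "vs_ml", "area_cm2",
                 "time_min", "conc_ug_per_ml"]
STANDARDS_COLUMNS = ["analyte", "nominal_conc_ug_per_ml", "signal"]
RESISTANCE_COLUMNS = ["well_id", "r1_ohm", "r0_ohm", "area_cm2", "context"]


class SchemaError(ValueError):
    """A CSV did not match its expected schema.

    Carries the offending file, and where known the row (1-based data
    row) and column, so the error message pinpoints the problem.
    """

    def __init__(self, file: str | Path, message: str,
                 row: int | None = None, column: str | None = None):
        self.file = str(file)
        self.row = row
        self.column = column
        where = f"{self.file}"
        if row is not None:
            where += f", row {row}"
        if column is not None:
            where += f", column '{column}'"
        super().__init__(f"{where}: {message}")


def _require_columns(df: pd.DataFrame, required: list[str], path: Path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(path, "missing required column", column=col)


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(path, "file not found")
    df = pd.read_csv(path, na_values=_NA_VALUES, keep_default_na=True)
    _require_columns(df, required, path)
    return df


def read_wells_csv(path: str | Path) -> list[WellTimeSeries]:
    """Read the tidy wells table into per-well time series.

    One input row per (well, time); rows are grouped by ``well_id`` and
    must agree on the well-level metadata. Numeric fields are validated
    row-by-row so the first bad cell is reported with its location.
    """
    path = Path(path)
    df = _read_csv(path, WELLS_COLUMNS)
    numeric = ["c0_ug_per_ml", "vr_ml", "vs_ml", "area_cm2", "time_min"]
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            raise SchemaError(path, "non-numeric or missing value",
                              row=int(bad.idxmax()) + 2, column=col)
        df[col] = vals
    df["conc_ug_per_ml"] = pd.to_numeric(df["conc_ug_per_ml"], errors="coerce")

    wells = []
    for wid, g in df.groupby("well_id", sort=False):
        meta_cols = ["condition", "compound", "direction", "c0_ug_per_ml",
                     "vr_ml", "vs_ml", "area_cm2"]
        for col in meta_cols:
            if g[col].nunique(dropna=False) > 1:
                raise SchemaError(path, f"well '{wid}' has inconsistent values",
                                  column=col)
        g = g.sort_values("time_min")
        first = g.iloc[0]
        try:
            wells.append(WellTimeSeries(
                well_id=str(wid), compound=str(first["compound"]),
                direction=str(first["direction"]),
                c0=float(first["c0_ug_per_ml"]), vr=float(first["vr_ml"]),
                vs=float(first["vs_ml"]), area=float(first["area_cm2"]),
                times=g["time_min"].to_numpy(dtype=float),
                concs=g["conc_ug_per_ml"].to_numpy(dtype=float),
                condition=None if pd.isna(first["condition"])
                else str(first["condition"])))
        except ValueError as exc:
            raise SchemaError(path, str(exc)) from exc
    if not wells:
        raise SchemaError(path, "no data rows")
    return wells


def write_wells_csv(wells: list[WellTimeSeries], path: str | Path) -> None:
    rows = []
    for w in wells:
        for t, c in zip(w.times, w.concs):
            rows.append({"well_id": w.well_id, "condition": w.condition or "",
                         "compound": w.compound, "direction": w.direction,
                         "c0_ug_per_ml": w.c0, "vr_ml": w.vr, "vs_ml": w.vs,
                         "area_cm2": w.area, "time_min": t,
                         "conc_ug_per_ml": c})
    write_frame(pd.DataFrame(rows, columns=WELLS_COLUMNS), path)


def read_standards_csv(path: str | Path) -> pd.DataFrame:
    """Calibration standards / QC samples: analyte, nominal conc, signal[, day]."""
    path = Path(path)
    df = _read_csv(path, STANDARDS_COLUMNS)
    for col in ("nominal_conc_ug_per_ml", "signal"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            raise SchemaError(path, "non-numeric or missing value",
                              row=int(bad.idxmax()) + 2, column=col)
        df[col] = vals
    return df


def read_resistance_csv(path: str | Path) -> list[TEERRecord]:
    """Electrical-resistance records for TEER monolayer-integrity QC."""
    path = Path(path)
    df = _read_csv(path, RESISTANCE_COLUMNS)
    records = []
    for i, row in df.iterrows():
        try:
            records.append(teer_record(
                str(row["well_id"]), float(row["r1_ohm"]), float(row["r0_ohm"]),
                float(row["area_cm2"]), str(row["context"])))
        except (TypeError, ValueError) as exc:
            raise SchemaError(path, str(exc), row=int(i) + 2) from exc
    return records


def write_frame(df: pd.DataFrame, path: str | Path, ndigits: int = 10) -> None:
    """Write a report frame as CSV, rendering NaN as the em dash.

    Floats are rounded to ``ndigits`` significant-stable decimals so
    output bytes are identical across runs on the same inputs.
    """
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].round(ndigits)
    out.to_csv(path, index=False, na_rep=MISSING, encoding="utf-8",
               lineterminator="\n")


def read_frame(path: str | Path) -> pd.DataFrame:
    """Read back a report frame written by :func:`write_frame`."""
    return pd.read_csv(path, na_values=_NA_VALUES, keep_default_na=True,
                       encoding="utf-8")
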