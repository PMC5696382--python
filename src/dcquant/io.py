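"""Table readers/writers with schema validation, plus small study utilities.

All tabular inputs and outputs are UTF-8 TSV/CSV with a required header
row, '.' decimal separator and no thousands separators; calibrations and
run metadata travel as JSON. Each schema names its required columns and
their types; readers fail loudly on missing/extra required columns,
non-numeric cells, or empty files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import DomainError, ExpressionMatrix

__all__ = [
    "SCHEMAS",
    "read_table",
    "write_table",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_json",
    "write_json",
    "tumor_volume",
]

# schema: column -> "num" | "str" | "bool"; columns in _OPTIONAL may be absent
SCHEMAS: dict[str, dict[str, str]] = {
    "three_cube": {"cell_id": "str", "I_DD": "num", "I_AA": "num",
                   "I_DA": "num", "label": "str", "time_s": "num"},
    "fret_trace": {"time_s": "num", "efficiency": "num"},
    "calcium_trace": {"well_id": "str", "time_s": "num", "F": "num"},
    "fusion_objects": {"object_id": "str", "fret": "num", "bead": "num",
                       "cell_ha_total": "num", "is_external": "bool"},
    "ros_objects": {"object_id": "str", "oxyburst": "num", "alexa568": "num",
                    "is_external": "bool"},
    "ph_calibration": {"ph": "num", "stack_id": "str", "ratio": "num"},
    "mfi_series": {"chase_min": "num", "mfi": "num"},
    "export_cells": {"cell_id": "str", "blue": "num", "green": "num",
                     "condition": "str"},
    "group_map": {"sample_id": "str", "group": "str"},
}
_OPTIONAL = {"three_cube": {"time_s"}}


def read_table(path, schema_name: str) -> pd.DataFrame:
    """Read a TSV against a registered schema; typed columns, loud errors."""
    if schema_name not in SCHEMAS:
        raise DomainError(f"unknown schema {schema_name!r}")
    path = Path(path)
    if not path.exists():
        raise DomainError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise DomainError(f"empty input file: {path}")
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise DomainError(f"input file has a header but no rows: {path}")
    schema = SCHEMAS[schema_name]
    optional = _OPTIONAL.get(schema_name, set())
    missing = (set(schema) - optional) - set(df.columns)
    if missing:
        raise DomainError(
            f"{path}: missing required column(s) for schema "
            f"{schema_name!r}: {sorted(missing)}"
        )
    for col, kind in schema.items():
        if col not in df.columns:
            continue
        if kind == "num":
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                rows = list(df.index[bad][:5])
                raise DomainError(
                    f"{path}: non-numeric value(s) in column {col!r} at row(s) {rows}"
                )
            df[col] = coerced
        elif kind == "bool":
            df[col] = df[col].astype(bool)
        else:
            df[col] = df[col].astype(str)
    return df


def write_table(table: pd.DataFrame, path) -> None:
    """Write a table as TSV (UTF-8, header row); round-trips via read_table."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)


def read_expression_matrix(matrix_path, groups_path) -> ExpressionMatrix:
    """Read a probes x samples TSV (first column probe_id, header = sample
    ids — a GEO series-matrix-like layout with metadata lines stripped)
    plus a two-column sample_id/group TSV."""
    matrix_path = Path(matrix_path)
    if not matrix_path.exists() or matrix_path.stat().st_size == 0:
        raise DomainError(f"missing or empty expression matrix: {matrix_path}")
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index.name = "probe_id"
    gm = read_table(groups_path, "group_map")
    groups = dict(zip(gm["sample_id"], gm["group"]))
    return ExpressionMatrix(values=values, groups=groups)


def write_expression_matrix(m: ExpressionMatrix, matrix_path, groups_path) -> None:
    Path(matrix_path).parent.mkdir(parents=True, exist_ok=True)
    m.values.to_csv(matrix_path, sep="\t")
    gm = pd.DataFrame(
        {"sample_id": list(m.values.columns),
         "group": [m.groups[s] for s in m.values.columns]}
    )
    write_table(gm, groups_path)


def read_json(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def write_json(obj: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def tumor_volume(r1: float, r2: float, r3: float, measures_are_radii: bool = False) -> float:
    """Ellipsoid tumor volume V = (4/3)*pi*r1*r2*r3 from caliper measurements.

    Caliper length/width/depth are diameters by default and are halved to
    semi-axes before the formula; pass ``measures_are_radii=True`` when the
    inputs are already semi-axes (mm). Returns mm^3.
    """
    vals = np.array([r1, r2, r3], dtype=float)
    if np.any(vals < 0) or not np.all(np.isfinite(vals)):
        raise DomainError("caliper measurements must be finite and >= 0")
    if not measures_are_radii:
        vals = vals / 2.0
    return float(4.0 / 3.0 * np.pi * np.prod(vals))
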