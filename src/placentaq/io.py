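"""Readers and writers for the pipeline's plain-text and image formats.

All tabular formats are strict: missing or extra columns, non-numeric
cells, and non-monotone time axes are rejected with errors naming the
offending row/column. Writers always emit a header and format floats with
6 significant digits, so a write/read round trip preserves values to that
precision.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .dce import SICurve
from .errors import DataError
from .histo import IntensityImage, SyncytiaField
from .stats import ExpressionMatrix

__all__ = [
    "read_curves_csv",
    "write_curves_csv",
    "read_syncytia_csv",
    "write_syncytia_csv",
    "read_cells_csv",
    "write_cells_csv",
    "read_image_tiff",
    "write_image_tiff",
    "read_expression",
    "write_expression",
    "write_table_csv",
]

CURVE_COLUMNS = ["placenta_id", "group", "time_s", "si"]
SYNCYTIA_COLUMNS = ["field_id", "syncytium_id", "nucleus_id", "positive"]
CELL_COLUMNS = ["field_id", "cell_id", "nucleus_count"]


def _read_strict(path: Path | str, columns: list[str], sep: str = ",") -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except Exception as exc:  # malformed CSV structure
        raise DataError(f"{path}: cannot parse: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    extra = [c for c in df.columns if c not in columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    if extra:
        raise DataError(f"{path}: unexpected columns {extra}")
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax())
        raise DataError(f"{path}: empty cell in data row {row}")
    return df[columns]


def _numeric(df: pd.DataFrame, column: str, path: Path | str) -> np.ndarray:
    converted = pd.to_numeric(df[column], errors="coerce")
    bad = converted.isna()
    if bad.any():
        row = int(bad.idxmax())
        raise DataError(
            f"{path}: non-numeric value {df[column][row]!r} in column {column!r}, "
            f"data row {row}"
        )
    return converted.to_numpy(dtype=float)


def write_curves_csv(curves: Sequence[SICurve], path: Path | str) -> None:
    """Write curves in long format (placenta_id, group, time_s, si)."""
    rows = []
    for c in curves:
        for t, v in zip(c.times, c.values):
            rows.append({"placenta_id": c.id, "group": c.group, "time_s": t, "si": v})
    write_table_csv(pd.DataFrame(rows, columns=CURVE_COLUMNS), path)


def read_curves_csv(path: Path | str) -> list[SICurve]:
    """Read long-format curves; times must be strictly increasing per placenta."""
    df = _read_strict(path, CURVE_COLUMNS)
    times = _numeric(df, "time_s", path)
    si = _numeric(df, "si", path)
    df = df.assign(time_s=times, si=si)
    curves = []
    for (pid, group), sub in df.groupby(["placenta_id", "group"], sort=True):
        t = sub["time_s"].to_numpy()
        if np.any(np.diff(t) <= 0):
            k = int(np.flatnonzero(np.diff(t) <= 0)[0])
            raise DataError(
                f"{path}: non-increasing time for placenta {pid!r} at data row "
                f"{int(sub.index[k + 1])} (column 'time_s')"
            )
        curves.append(SICurve(times=t, values=sub["si"].to_numpy(), id=str(pid), group=str(group)))
    return curves


def write_syncytia_csv(fields: Sequence[SyncytiaField], path: Path | str) -> None:
    rows = [
        {"field_id": f.field_id, "syncytium_id": j, "nucleus_id": k, "positive": flag}
        for f in fields
        for j, syn in enumerate(f.syncytia)
        for k, flag in enumerate(syn)
    ]
    write_table_csv(pd.DataFrame(rows, columns=SYNCYTIA_COLUMNS), path)


def read_syncytia_csv(path: Path | str) -> list[SyncytiaField]:
    df = _read_strict(path, SYNCYTIA_COLUMNS)
    positive = _numeric(df, "positive", path)
    if not np.isin(positive, (0, 1)).all():
        row = int(np.flatnonzero(~np.isin(positive, (0, 1)))[0])
        raise DataError(f"{path}: column 'positive' must be 0/1, data row {row}")
    df = df.assign(positive=positive.astype(int))
    fields = []
    for fid, fsub in df.groupby("field_id", sort=True):
        syncytia = tuple(
            tuple(ssub["positive"]) for _, ssub in fsub.groupby("syncytium_id", sort=True)
        )
        fields.append(SyncytiaField(field_id=str(fid), syncytia=syncytia))
    return fields


def write_cells_csv(
    fields: dict[str, Sequence[int]], path: Path | str
) -> None:
    """Write per-cell nucleus counts, one table of fields."""
    rows = [
        {"field_id": fid, "cell_id": i, "nucleus_count": int(n)}
        for fid, counts in fields.items()
        for i, n in enumerate(counts)
    ]
    write_table_csv(pd.DataFrame(rows, columns=CELL_COLUMNS), path)


def read_cells_csv(path: Path | str) -> dict[str, list[int]]:
    df = _read_strict(path, CELL_COLUMNS)
    counts = _numeric(df, "nucleus_count", path)
    if np.any(counts < 1) or np.any(counts != counts.astype(int)):
        row = int(np.flatnonzero((counts < 1) | (counts != counts.astype(int)))[0])
        raise DataError(f"{path}: invalid nucleus_count at data row {row}")
    df = df.assign(nucleus_count=counts.astype(int))
    return {
        str(fid): list(sub["nucleus_count"]) for fid, sub in df.groupby("field_id", sort=True)
    }


def write_image_tiff(image: IntensityImage, path: Path | str) -> None:
    tifffile.imwrite(str(path), image.pixels.astype(np.float32))
    if image.mask is not None:
        mask_path = Path(path).with_suffix(".mask.tif")
        tifffile.imwrite(str(mask_path), image.mask.astype(np.uint8))


def read_image_tiff(
    path: Path | str, mask_path: Path | str | None = None, channel: str = "SA-b-gal"
) -> IntensityImage:
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    pixels = np.asarray(tifffile.imread(str(path)), dtype=float)
    mask = None
    if mask_path is not None:
        mask = np.asarray(tifffile.imread(str(mask_path)), dtype=bool)
    return IntensityImage(pixels=pixels, mask=mask, channel=channel)


def write_expression(
    expr: ExpressionMatrix, matrix_path: Path | str, sheet_path: Path | str
) -> None:
    """Write a genes × samples TSV plus a sample sheet CSV (sample, group)."""
    out = expr.values.copy()
    out.index.name = "gene"
    out.map(lambda v: float(f"{v:.6g}")).to_csv(matrix_path, sep="\t")
    sheet = pd.DataFrame({"sample": expr.groups.index, "group": expr.groups.to_numpy()})
    sheet.to_csv(sheet_path, index=False)


def read_expression(matrix_path: Path | str, sheet_path: Path | str) -> ExpressionMatrix:
    matrix_path, sheet_path = Path(matrix_path), Path(sheet_path)
    for p in (matrix_path, sheet_path):
        if not p.exists():
            raise DataError(f"input file not found: {p}")
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    non_numeric = [c for c in values.columns if not pd.api.types.is_numeric_dtype(values[c])]
    if non_numeric:
        raise DataError(f"{matrix_path}: non-numeric expression column {non_numeric[0]!r}")
    sheet = _read_strict(sheet_path, ["sample", "group"])
    groups = pd.Series(sheet["group"].to_numpy(), index=sheet["sample"], name="group")
    return ExpressionMatrix(values=values, groups=groups)


def write_table_csv(table: pd.DataFrame, path: Path | str) -> None:
    """Write any result table with 6-significant-digit floats and a header."""
    table.to_csv(path, index=False, float_format="%.6g")
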