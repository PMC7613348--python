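"""CSV sample tables: one wide file holding paired input/output spectra.

Column layout: ``scene,row,col,class`` then the input radiance columns
``L_<wavelength>`` and the reference SIF columns ``F_<wavelength>``, with
wavelengths printed in nm. Lines starting with ``#`` are metadata comments
and are ignored on read.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .datamodel import BandGrid, SampleTable, SpectralMatrix
from .errors import FormatError

_META = ["scene", "row", "col", "class"]


def write_sample_table(table: SampleTable, path: str | os.PathLike,
                       comment: str = "") -> None:
    """Write a sample table as wide CSV; ``comment`` goes into a ``#`` line."""
    cols = {
        "scene": table.scene,
        "row": table.row,
        "col": table.col,
        "class": table.label,
    }
    for j, wl in enumerate(table.X.grid.wavelengths):
        cols[f"L_{wl:.4f}"] = table.X.values[:, j]
    for j, wl in enumerate(table.Y.grid.wavelengths):
        cols[f"F_{wl:.4f}"] = table.Y.values[:, j]
    df = pd.DataFrame(cols)
    with open(path, "w", newline="") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, index=False, float_format="%.8g")


def _grid_from_columns(names: list[str], prefix: str, label: str) -> BandGrid:
    wl = []
    for name in names:
        try:
            wl.append(float(name[len(prefix):]))
        except ValueError as exc:
            raise FormatError(f"cannot parse wavelength from column '{name}'") from exc
    arr = np.asarray(wl)
    if arr.size > 1 and not np.all(np.diff(arr) > 0):
        raise FormatError(f"{prefix}* wavelengths are not strictly increasing")
    return BandGrid(arr, label=label)


def read_sample_table(path: str | os.PathLike) -> SampleTable:
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.ParserError as exc:
        raise FormatError(f"malformed sample table: {exc}") from exc
    missing = [c for c in _META if c not in df.columns]
    if missing:
        raise FormatError(f"sample table missing columns {missing}")
    l_cols = [c for c in df.columns if c.startswith("L_")]
    f_cols = [c for c in df.columns if c.startswith("F_")]
    if not l_cols or not f_cols:
        raise FormatError("sample table needs both L_* and F_* spectral columns")
    if df[l_cols + f_cols].isna().any().any():
        raise FormatError("ragged or missing spectral values in sample table")
    return SampleTable(
        scene=df["scene"].astype(str).to_numpy(dtype=object),
        row=df["row"].to_numpy(dtype=int),
        col=df["col"].to_numpy(dtype=int),
        label=df["class"].to_numpy(dtype=int),
        X=SpectralMatrix(df[l_cols].to_numpy(dtype=float),
                         _grid_from_columns(l_cols, "L_", "input")),
        Y=SpectralMatrix(df[f_cols].to_numpy(dtype=float),
                         _grid_from_columns(f_cols, "F_", "output")),
    )
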