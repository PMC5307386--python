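"""Readers and writers: plot tables, Esri ASCII grids, JSON summaries."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .interpolation import NODATA, GridSpec, PredictionGrid

log = logging.getLogger("socmap")

#: canonical plot-table columns; coordinates are projected metres
PLOT_COLUMNS = ("id", "x", "y", "elevation", "slope", "aspect",
                "stock_0_20", "stock_20_40", "stock_40_60", "stock_0_60")
STOCK_COLUMNS = PLOT_COLUMNS[6:]
MANDATORY = ("id", "x", "y")


class SchemaError(ValueError):
    pass


def read_plot_table(path, layers=None) -> pd.DataFrame:
    """Read and validate a delimited plot table.

    Rows missing a stock in any requested layer are dropped (and counted in
    the log).  Coordinates must look like projected metres: a table whose
    coordinates all fit inside lon/lat ranges is rejected.
    """
    path = Path(path)
    import csv
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except (pd.errors.EmptyDataError, csv.Error) as exc:
        raise SchemaError(f"{path} is empty or not a delimited table: {exc}")
    layers = list(layers) if layers is not None else [
        c for c in STOCK_COLUMNS if c in df.columns]
    missing = [c for c in (*MANDATORY, *layers) if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    for c in ("x", "y"):
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[vals.isna()].tolist()
        if bad:
            raise SchemaError(f"non-numeric {c!r} in rows {bad[:10]}")
        df[c] = vals
    if len(df) and (df["x"].abs() <= 360).all() and (df["y"].abs() <= 90).all():
        raise SchemaError(
            "coordinates look like lon/lat degrees; project them to metric "
            "coordinates first")
    n0 = len(df)
    df = df.dropna(subset=layers).reset_index(drop=True)
    if n0 - len(df):
        log.info("dropped %d of %d rows with missing stock values",
                 n0 - len(df), n0)
    if not len(df):
        raise SchemaError("no usable rows after dropping incomplete plots")
    return df


def write_plot_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_esri_ascii(grid: PredictionGrid, path, nodata: float = NODATA,
                     variance: bool = False) -> None:
    """Write a prediction (or kriging-variance) surface as Esri ASCII.

    Header fields: ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value.
    Data rows run north to south, as the format requires.
    """
    spec = grid.spec
    arr = grid.kriging_variance if variance else grid.prediction
    if arr is None:
        raise ValueError("grid has no variance surface")
    data = np.where(np.isfinite(arr) & grid.mask, arr, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.nx}\n")
        fh.write(f"nrows {spec.ny}\n")
        fh.write(f"xllcorner {spec.origin[0]:.6f}\n")
        fh.write(f"yllcorner {spec.origin[1]:.6f}\n")
        fh.write(f"cellsize {spec.cell_size:.6f}\n")
        fh.write(f"NODATA_value {nodata:g}\n")
        for row in data[::-1]:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def read_esri_ascii(path) -> PredictionGrid:
    """Read an Esri ASCII grid back into a PredictionGrid (method 'raster')."""
    header = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in (
                    "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                    "nodata_value"):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    arr = np.array(rows)[::-1]  # back to row 0 = south
    nodata = header.get("nodata_value", NODATA)
    mask = arr != nodata
    arr = np.where(mask, arr, np.nan)
    spec = GridSpec(origin=(header["xllcorner"], header["yllcorner"]),
                    cell_size=header["cellsize"], nx=int(header["ncols"]),
                    ny=int(header["nrows"]), mask=mask)
    return PredictionGrid(spec=spec, prediction=arr, method="raster")


def grid_to_table(grid: PredictionGrid) -> pd.DataFrame:
    """Cell-centre dump of a prediction grid (masked-in cells only)."""
    xs, ys = grid.spec.cell_centers()
    jj, ii = np.meshgrid(np.arange(grid.spec.nx), np.arange(grid.spec.ny))
    keep = grid.mask & np.isfinite(grid.prediction)
    out = pd.DataFrame({
        "x": xs[jj[keep]],
        "y": ys[ii[keep]],
        "prediction": grid.prediction[keep],
    })
    if grid.kriging_variance is not None:
        out["kriging_variance"] = grid.kriging_variance[keep]
    return out
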