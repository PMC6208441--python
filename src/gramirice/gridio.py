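"""Plain-text raster and tabular I/O.

Grids are written as ESRI ASCII grid (.asc): a six-line header (ncols, nrows,
xllcorner, yllcorner, cellsize, nodata_value) followed by row-major values,
row 0 = north. The georeference beyond what the header carries (CRS, full
affine) goes to a JSON sidecar `<name>.asc.json`. Observation tables travel
as CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GridSpec", "write_ascii_grid", "read_ascii_grid", "write_obs_csv", "read_obs_csv"]

OBS_COLUMNS = ["pixel_id", "doy", "sza_deg", "vza_deg", "raa_deg", "red", "nir"]


@dataclass(frozen=True)
class GridSpec:
    """Raster georeference: (row, col) 0-based, row 0 = north, north-up affine."""

    rows: int
    cols: int
    transform: tuple = (500.0, 0.0, 300000.0, 0.0, -500.0, 4300000.0)  # a,b,c,d,e,f
    crs: str = "EPSG:32652"
    nodata: float = -9999.0

    def __post_init__(self):
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("grid dimensions must be positive")

    @property
    def cell_size(self) -> float:
        return abs(self.transform[0])

    @property
    def cell_area(self) -> float:
        return abs(self.transform[0] * self.transform[4])


def write_ascii_grid(path, array: np.ndarray, spec: GridSpec) -> None:
    arr = np.asarray(array, dtype=float)
    if arr.shape != (spec.rows, spec.cols):
        raise ValueError("array shape does not match GridSpec")
    a, _, c, _, e, f = spec.transform
    body = np.where(np.isfinite(arr), arr, spec.nodata)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.cols}\n")
        fh.write(f"nrows {spec.rows}\n")
        fh.write(f"xllcorner {c:.6f}\n")
        fh.write(f"yllcorner {f + e * spec.rows:.6f}\n")
        fh.write(f"cellsize {abs(a):.6f}\n")
        fh.write(f"nodata_value {spec.nodata}\n")
        np.savetxt(fh, body, fmt="%.8g")
    sidecar = {"crs": spec.crs, "transform": list(spec.transform)}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_ascii_grid(path):
    """Returns (array with NaN at nodata, GridSpec); restores the JSON sidecar if present."""
    path = Path(path)
    header = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        arr = np.loadtxt(fh)
    rows, cols = int(header["nrows"]), int(header["ncols"])
    arr = arr.reshape(rows, cols)
    nodata = header["nodata_value"]
    cell = header["cellsize"]
    transform = (
        cell, 0.0, header["xllcorner"], 0.0, -cell, header["yllcorner"] + cell * rows,
    )
    crs = "EPSG:32652"
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        crs = meta.get("crs", crs)
        transform = tuple(meta.get("transform", transform))
    spec = GridSpec(rows, cols, tuple(transform), crs, nodata)
    return np.where(arr == nodata, np.nan, arr), spec


def write_obs_csv(path, obs: pd.DataFrame) -> None:
    """Angular-observation CSV: pixel_id, doy, sza_deg, vza_deg, raa_deg, red, nir."""
    df = obs.rename(columns={"sza": "sza_deg", "vza": "vza_deg", "raa": "raa_deg"})
    if "pixel_id" not in df:
        df = df.assign(pixel_id=0)
    df[OBS_COLUMNS].to_csv(path, index=False)


def read_obs_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return df.rename(columns={"sza_deg": "sza", "vza_deg": "vza", "raa_deg": "raa"})
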