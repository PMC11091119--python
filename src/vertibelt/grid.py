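"""Square-cell rasters and plain-text (ESRI ASCII grid) I/O.

The package works entirely on axis-aligned rasters with square cells.  Row 0 is
the northernmost row, matching the ASCII-grid convention; ``(xll, yll)`` is the
outer corner of the south-west cell.  Elevation rasters use ``float`` values
with NaN marking nodata; categorical rasters (stand ids) use integers with a
sentinel nodata value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InputError

ASCII_NODATA = -9999.0


@dataclass
class Raster:
    """A georeferenced square-cell grid.

    Parameters
    ----------
    values:
        2-D array; row 0 is the top (north) row.
    cell_size:
        Cell edge length in metres.
    xll, yll:
        Map coordinates of the lower-left corner of the grid.
    """

    values: np.ndarray
    cell_size: float
    xll: float = 0.0
    yll: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise InputError("raster values must be a 2-D array")
        if self.cell_size <= 0:
            raise InputError("cell_size must be positive")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full grid footprint."""
        return (
            self.xll,
            self.yll,
            self.xll + self.n_cols * self.cell_size,
            self.yll + self.n_rows * self.cell_size,
        )

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    def cell_index(self, x, y):
        """Row/col of the cell containing map point(s) (x, y).

        Points outside the footprint get index -1 in both row and col.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.xll) / self.cell_size).astype(int)
        row_from_bottom = np.floor((y - self.yll) / self.cell_size).astype(int)
        row = self.n_rows - 1 - row_from_bottom
        bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        col = np.where(bad, -1, col)
        row = np.where(bad, -1, row)
        return row, col

    def value_at(self, x, y, fill=np.nan):
        """Containing-cell lookup; *fill* for points outside the footprint."""
        row, col = self.cell_index(x, y)
        out = np.where(
            (row >= 0) & (col >= 0),
            self.values[np.clip(row, 0, None), np.clip(col, 0, None)],
            fill,
        )
        return out

    def finite_range(self) -> tuple[float, float]:
        vals = self.values[np.isfinite(self.values)]
        if vals.size == 0:
            raise InputError("raster contains no finite values")
        return float(vals.min()), float(vals.max())

    # -- plain-text I/O ----------------------------------------------------

    def write_ascii(self, path: str | Path, fmt: str = "%.3f") -> Path:
        """Write as an ESRI ASCII grid (nodata = -9999)."""
        path = Path(path)
        vals = np.array(self.values, dtype=float)
        vals[~np.isfinite(vals)] = ASCII_NODATA
        header = (
            f"ncols {self.n_cols}\n"
            f"nrows {self.n_rows}\n"
            f"xllcorner {self.xll:.6f}\n"
            f"yllcorner {self.yll:.6f}\n"
            f"cellsize {self.cell_size:.6f}\n"
            f"NODATA_value {ASCII_NODATA:.0f}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, vals, fmt=fmt)
        return path

    @classmethod
    def read_ascii(cls, path: str | Path) -> "Raster":
        path = Path(path)
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            values = np.loadtxt(fh)
        values = np.atleast_2d(values)
        nodata = header.get("nodata_value", ASCII_NODATA)
        values[values == nodata] = np.nan
        grid = cls(
            values=values,
            cell_size=header["cellsize"],
            xll=header.get("xllcorner", 0.0),
            yll=header.get("yllcorner", 0.0),
        )
        if grid.n_rows != int(header["nrows"]) or grid.n_cols != int(header["ncols"]):
            raise InputError(f"ASCII grid {path} data block does not match its header")
        return grid


# An elevation raster is just a float Raster; the alias keeps signatures readable.
ElevationGrid = Raster


@dataclass
class StandMap:
    """Per-cell stand raster plus a stand attribute table.

    ``stand_id`` assigns every cell to a stand patch (int; -1 = outside map).
    ``attributes`` is indexed by stand id and carries ``dominant_species`` and
    ``composition`` (tenths-code string, empty for non-forest stands); the
    classifier adds a ``forest_type`` column.
    """

    stand_id: np.ndarray
    attributes: "object"  # pandas.DataFrame, imported lazily to keep grid deps light
    cell_size: float
    xll: float = 0.0
    yll: float = 0.0

    def __post_init__(self) -> None:
        self.stand_id = np.asarray(self.stand_id, dtype=int)
        if self.stand_id.ndim != 2:
            raise InputError("stand_id must be a 2-D array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.stand_id.shape

    def as_raster(self) -> Raster:
        return Raster(self.stand_id.astype(float), self.cell_size, self.xll, self.yll)

    def cell_column(self, column: str, fill="") -> np.ndarray:
        """Broadcast an attribute column onto the cell grid (object array)."""
        mapping = self.attributes[column].to_dict()
        flat = self.stand_id.ravel()
        out = np.array([mapping.get(sid, fill) for sid in flat], dtype=object)
        return out.reshape(self.shape)

    def write(self, raster_path: str | Path, table_path: str | Path) -> None:
        self.as_raster().write_ascii(raster_path, fmt="%d")
        self.attributes.to_csv(table_path, index_label="stand_id")

    @classmethod
    def read(cls, raster_path: str | Path, table_path: str | Path) -> "StandMap":
        import pandas as pd

        raster = Raster.read_ascii(raster_path)
        table = pd.read_csv(table_path, index_col="stand_id", keep_default_na=False)
        vals = raster.values.copy()
        vals[~np.isfinite(vals)] = -1
        return cls(
            stand_id=vals.astype(int),
            attributes=table,
            cell_size=raster.cell_size,
            xll=raster.xll,
            yll=raster.yll,
        )
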