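"""Georeferenced landscape rasters (elevation + land/sea mask).

Rasters are stored row 0 = northernmost (image convention) and serialised
as ESRI ASCII grids (plain text, readable by GDAL/QGIS): one ``.asc`` for
elevation and one for the sea mask (1 = sea, 0 = land).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["LandscapeGrid", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class LandscapeGrid:
    """Elevation raster with a boolean sea mask and lon/lat georeferencing.

    ``xllcorner``/``yllcorner`` are the lon/lat of the lower-left corner of
    the lower-left cell; ``cell_size`` is in degrees.  Elevation is in
    metres and is ignored (conventionally 0) on sea cells.
    """

    elevation: np.ndarray
    sea_mask: np.ndarray
    xllcorner: float
    yllcorner: float
    cell_size: float

    def __post_init__(self) -> None:
        self.elevation = np.asarray(self.elevation, dtype=float)
        self.sea_mask = np.asarray(self.sea_mask, dtype=bool)
        if self.elevation.ndim != 2 or self.elevation.shape != self.sea_mask.shape:
            raise ValueError("elevation and sea_mask must be 2-D with equal shape")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        land = ~self.sea_mask
        if not np.isfinite(self.elevation[land]).all():
            raise ValueError("elevation must be finite on land cells")

    @property
    def n_rows(self) -> int:
        return self.elevation.shape[0]

    @property
    def n_cols(self) -> int:
        return self.elevation.shape[1]

    @property
    def n_cells(self) -> int:
        return self.elevation.size

    def cell_center(self, row, col):
        """Lon/lat of cell centre(s); row 0 is the northern edge."""
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.xllcorner + (col + 0.5) * self.cell_size
        lat = self.yllcorner + (self.n_rows - row - 0.5) * self.cell_size
        return lon, lat

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Row/col of the cell containing a lon/lat point."""
        col = int(np.floor((lon - self.xllcorner) / self.cell_size))
        row = int(self.n_rows - 1 - np.floor((lat - self.yllcorner) / self.cell_size))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"point ({lon}, {lat}) is outside the grid")
        return row, col

    def node_index(self, row: int, col: int) -> int:
        return row * self.n_cols + col

    def write(self, directory, prefix: str = "landscape") -> None:
        """Write ``<prefix>_elevation.asc`` and ``<prefix>_seamask.asc``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        hdr = dict(
            xllcorner=self.xllcorner,
            yllcorner=self.yllcorner,
            cellsize=self.cell_size,
        )
        write_ascii_grid(
            directory / f"{prefix}_elevation.asc", self.elevation, **hdr
        )
        write_ascii_grid(
            directory / f"{prefix}_seamask.asc",
            self.sea_mask.astype(float),
            **hdr,
        )

    @classmethod
    def read(cls, elevation_path, seamask_path) -> "LandscapeGrid":
        elev, x, y, cs = read_ascii_grid(elevation_path)
        mask, x2, y2, cs2 = read_ascii_grid(seamask_path)
        if elev.shape != mask.shape or (x, y, cs) != (x2, y2, cs2):
            raise ValueError("elevation and sea-mask rasters are not aligned")
        return cls(elev, mask > 0.5, x, y, cs)


def write_ascii_grid(path, values, xllcorner, yllcorner, cellsize, nodata=-9999.0):
    values = np.asarray(values, dtype=float)
    nrows, ncols = values.shape
    out = np.where(np.isfinite(values), values, nodata)
    with open(path, "w") as fh:
        fh.write(
            f"ncols {ncols}\nnrows {nrows}\n"
            f"xllcorner {xllcorner!r}\nyllcorner {yllcorner!r}\n"
            f"cellsize {cellsize!r}\nNODATA_value {nodata!r}\n"
        )
        for row in out:
            fh.write(" ".join(f"{float(v):.10g}" for v in row) + "\n")


def read_ascii_grid(path):
    """Read an ESRI ASCII grid; returns (values, xllcorner, yllcorner, cellsize)."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    values = np.array(rows, dtype=float)
    nodata = header.get("nodata_value", -9999.0)
    values[values == nodata] = np.nan
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"raster {path} body does not match its header")
    return (
        values,
        header["xllcorner"],
        header["yllcorner"],
        header["cellsize"],
    )
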