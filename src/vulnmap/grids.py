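"""Georeferenced scalar grids (flood depth, temperature summaries).

A :class:`HazardGrid` is a regular, axis-aligned raster in a projected
planar coordinate system: a 2-D array plus the coordinates of its lower-left
corner and a square cell size.  Row 0 is the southernmost row.  Cell
ownership is half-open — a point (x, y) belongs to the cell
[x0 + j*c, x0 + (j+1)*c) x [y0 + i*c, y0 + (i+1)*c) — so every point maps
to exactly one cell and results cannot depend on tie-breaking at edges.

Grids serialise to/from the ESRI ASCII grid format (plain text), which any
GIS reads directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

__all__ = ["HazardGrid", "DEFAULT_CRS"]

#: Name of the synthetic planar CRS (unit = metre-like planar unit).
DEFAULT_CRS = "synthetic:planar"


@dataclass
class HazardGrid:
    """Regular raster with lower-left georeferencing.

    Attributes
    ----------
    values : np.ndarray
        2-D float array, shape (ny, nx); row 0 is the southern edge.
    xmin, ymin : float
        Coordinates of the lower-left corner of the grid.
    cell_size : float
        Square cell edge length, in planar units.
    nodata : float
        Sentinel written to file for missing cells; in memory missing cells
        are NaN.
    crs : str
        Coordinate system tag; layers must agree before they are combined.
    metadata : dict
        Free-form provenance (scenario, variable name, units, ...).
    """

    values: np.ndarray
    xmin: float = 0.0
    ymin: float = 0.0
    cell_size: float = 1.0
    nodata: float = -9999.0
    crs: str = DEFAULT_CRS
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ParameterError(f"grid values must be 2-D, got shape {self.values.shape}")
        if self.cell_size <= 0:
            raise ParameterError(f"cell_size must be positive, got {self.cell_size}")

    @property
    def ny(self) -> int:
        return self.values.shape[0]

    @property
    def nx(self) -> int:
        return self.values.shape[1]

    @property
    def xmax(self) -> float:
        return self.xmin + self.nx * self.cell_size

    @property
    def ymax(self) -> float:
        return self.ymin + self.ny * self.cell_size

    def x_centers(self) -> np.ndarray:
        return self.xmin + (np.arange(self.nx) + 0.5) * self.cell_size

    def y_centers(self) -> np.ndarray:
        return self.ymin + (np.arange(self.ny) + 0.5) * self.cell_size

    def cell_index(self, xs, ys) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map points to (row, col) under the half-open ownership rule.

        Returns (rows, cols, inside) where ``inside`` flags points within the
        grid extent; rows/cols of outside points are clipped and must be
        masked by the caller.
        """
        xs = np.asarray(xs, dtype=float)
        ys = np.asarray(ys, dtype=float)
        cols = np.floor((xs - self.xmin) / self.cell_size).astype(int)
        rows = np.floor((ys - self.ymin) / self.cell_size).astype(int)
        inside = (cols >= 0) & (cols < self.nx) & (rows >= 0) & (rows < self.ny)
        return np.clip(rows, 0, self.ny - 1), np.clip(cols, 0, self.nx - 1), inside

    def sample(self, xs, ys) -> tuple[np.ndarray, np.ndarray]:
        """Grid value at each point (NaN where missing) and an inside mask."""
        rows, cols, inside = self.cell_index(xs, ys)
        vals = self.values[rows, cols]
        vals = np.where(inside, vals, np.nan)
        return vals, inside

    # -- ESRI ASCII grid serialisation ---------------------------------
    def to_ascii(self, path) -> None:
        """Write the grid as an ESRI ASCII grid (text; row order north-first)."""
        header = (
            f"ncols {self.nx}\n"
            f"nrows {self.ny}\n"
            f"xllcorner {self.xmin!r}\n"
            f"yllcorner {self.ymin!r}\n"
            f"cellsize {self.cell_size!r}\n"
            f"NODATA_value {self.nodata!r}\n"
        )
        body = np.where(np.isnan(self.values), self.nodata, self.values)[::-1]
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(header)
            np.savetxt(fh, body, fmt="%.6g")

    @classmethod
    def from_ascii(cls, path, crs: str = DEFAULT_CRS, metadata: dict | None = None) -> "HazardGrid":
        with open(path, encoding="utf-8") as fh:
            hdr = {}
            for _ in range(6):
                key, val = fh.readline().split()
                hdr[key.lower()] = float(val)
            body = np.loadtxt(fh)
        body = np.atleast_2d(body)[::-1].copy()
        nodata = hdr.get("nodata_value", -9999.0)
        body[body == nodata] = np.nan
        return cls(
            values=body,
            xmin=hdr["xllcorner"],
            ymin=hdr["yllcorner"],
            cell_size=hdr["cellsize"],
            nodata=nodata,
            crs=crs,
            metadata=metadata or {},
        )
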