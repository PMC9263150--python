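"""Lightweight georeferenced raster container with plain-text (ESRI ASCII grid) I/O.

Convention: row 0 is the northern edge, columns increase eastward, pixels are
half-open square cells of side ``cell_size`` metres, and the centre of pixel
``(row, col)`` maps to ``(x_origin + (col + 0.5) * cell_size,
y_origin - (row + 0.5) * cell_size)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError

__all__ = ["GridTransform", "Raster", "read_ascii_grid", "write_ascii_grid"]


@dataclass(frozen=True)
class GridTransform:
    """North-up affine georeference: origin at the north-west corner."""

    x_origin: float
    y_origin: float
    cell_size: float

    def cell_center(self, row, col):
        """Map (row, col) indices to projected (x, y) centre coordinates."""
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        x = self.x_origin + (col + 0.5) * self.cell_size
        y = self.y_origin - (row + 0.5) * self.cell_size
        return x, y

    def node(self, row, col):
        """Map fractional grid coordinates (cell-corner lattice) to (x, y)."""
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        return (self.x_origin + col * self.cell_size,
                self.y_origin - row * self.cell_size)


@dataclass
class Raster:
    """A single-band raster: a 2-D array plus georeference and nodata."""

    data: np.ndarray
    transform: GridTransform
    crs: str = "local-metric"
    nodata: float | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"raster data must be 2-D, got {self.data.ndim}-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def cell_size(self) -> float:
        return self.transform.cell_size

    def valid_mask(self) -> np.ndarray:
        if self.nodata is None:
            return np.ones(self.shape, dtype=bool)
        return self.data != self.nodata

    def aligned_with(self, other: "Raster") -> bool:
        return (self.shape == other.shape
                and self.transform == other.transform
                and self.crs == other.crs)

    def like(self, data: np.ndarray, nodata=None) -> "Raster":
        """New raster sharing this one's georeference."""
        return Raster(data, self.transform, self.crs, nodata)


def require_aligned(*rasters: Raster) -> None:
    first = rasters[0]
    for r in rasters[1:]:
        if not first.aligned_with(r):
            raise AlignmentError(
                f"rasters misaligned: {first.shape}/{first.transform} vs "
                f"{r.shape}/{r.transform}")


def write_ascii_grid(path, raster: Raster, fmt: str = "%.6g") -> None:
    """Write an ESRI ASCII grid (.asc). Boolean rasters are stored as 0/1."""
    nrows, ncols = raster.shape
    t = raster.transform
    nodata = raster.nodata if raster.nodata is not None else -9999
    data = raster.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
        fmt = "%d"
    elif np.issubdtype(data.dtype, np.integer):
        fmt = "%d"
    yll = t.y_origin - nrows * t.cell_size
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {t.x_origin!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {t.cell_size!r}\n")
        fh.write(f"NODATA_value {nodata}\n")
        np.savetxt(fh, data, fmt=fmt)


def read_ascii_grid(path, dtype=float, crs: str = "local-metric") -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        data = np.loadtxt(fh, dtype=dtype)
    data = np.atleast_2d(data)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if data.shape != (nrows, ncols):
        raise ValueError(f"grid shape {data.shape} != header ({nrows}, {ncols})")
    cell = header["cellsize"]
    transform = GridTransform(header["xllcorner"],
                              header["yllcorner"] + nrows * cell, cell)
    return Raster(data, transform, crs=crs, nodata=header.get("nodata_value"))
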