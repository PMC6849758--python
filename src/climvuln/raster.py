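"""Raster grids with ESRI ASCII grid serialization.

The ESRI ASCII format is a plain-text header (ncols/nrows/xllcorner/
yllcorner/cellsize/NODATA_value) followed by rows of cell values, top row
first.  All landscape layers (climate, suitability, cost and current
surfaces) use this representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Grid:
    """A single raster layer.

    `data` is stored with row 0 = northernmost row (as in the file format);
    nodata cells hold NaN in memory and `nodata` in files.
    """

    data: np.ndarray
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    cellsize: float = 1.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def copy_with(self, data: np.ndarray) -> "Grid":
        if np.shape(data) != self.shape:
            raise ValueError("replacement data must keep the grid shape")
        return Grid(np.asarray(data, float), self.xllcorner, self.yllcorner,
                    self.cellsize, self.nodata)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(x, y) of the centre of a cell; row 0 is the top row."""
        nrows = self.shape[0]
        x = self.xllcorner + (col + 0.5) * self.cellsize
        y = self.yllcorner + (nrows - row - 0.5) * self.cellsize
        return x, y

    def write_ascii(self, path) -> None:
        nrows, ncols = self.shape
        out = np.where(np.isnan(self.data), self.nodata, self.data)
        with open(path, "w") as fh:
            fh.write(f"ncols {ncols}\n")
            fh.write(f"nrows {nrows}\n")
            fh.write(f"xllcorner {self.xllcorner}\n")
            fh.write(f"yllcorner {self.yllcorner}\n")
            fh.write(f"cellsize {self.cellsize}\n")
            fh.write(f"NODATA_value {self.nodata}\n")
            for row in out:
                fh.write(" ".join(format(v, ".10g") for v in row) + "\n")


def read_ascii(path) -> Grid:
    """Read an ESRI ASCII grid; nodata values become NaN."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value"} and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    for req in ("ncols", "nrows"):
        if req not in header:
            raise ValueError(f"missing '{req}' in ESRI ASCII header: {path}")
    data = np.concatenate([np.asarray(r, float) for r in rows])
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if data.size != nrows * ncols:
        raise ValueError(
            f"expected {nrows * ncols} cells, found {data.size} in {path}"
        )
    data = data.reshape(nrows, ncols)
    nodata = header.get("nodata_value", -9999.0)
    data = np.where(data == nodata, np.nan, data)
    return Grid(data, header.get("xllcorner", 0.0), header.get("yllcorner", 0.0),
                header.get("cellsize", 1.0), nodata)
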