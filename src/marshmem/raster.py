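"""Minimal single-band raster container with ESRI ASCII grid I/O.

The ASCII grid (.asc) is a plain-text format: a six-line header
(ncols/nrows/xllcorner/yllcorner/cellsize/nodata_value) followed by the
grid values row-major from the north-west corner.  In memory, nodata cells
are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np


class RasterError(ValueError):
    pass


@dataclass
class Raster:
    """2-D grid with square pixels.

    data : float array, NaN = nodata
    cellsize : pixel edge length, metres
    xll, yll : coordinates of the lower-left corner
    """

    data: np.ndarray
    cellsize: float = 1.0
    xll: float = 0.0
    yll: float = 0.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise RasterError("raster data must be 2-D")
        if self.cellsize <= 0:
            raise RasterError("cellsize must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def pixel_area_m2(self) -> float:
        return self.cellsize * self.cellsize

    def aligned_with(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and self.cellsize == other.cellsize
            and self.xll == other.xll
            and self.yll == other.yll
        )

    def with_data(self, data: np.ndarray) -> "Raster":
        """Same grid, new values."""
        if data.shape != self.shape:
            raise RasterError("shape mismatch")
        return replace(self, data=np.asarray(data, dtype=float))


def read_ascii_grid(path) -> Raster:
    lines = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(lines) and len(header) < 6:
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner",
            "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise RasterError(f"ASCII grid {path} missing header field {key}")
    data = np.loadtxt(lines[i:], dtype=float)
    data = np.atleast_2d(data)
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise RasterError(
            f"ASCII grid {path}: data shape {data.shape} does not match header"
        )
    nodata = header.get("nodata_value", -9999.0)
    data[data == nodata] = np.nan
    return Raster(
        data=data,
        cellsize=header["cellsize"],
        xll=header.get("xllcorner", 0.0),
        yll=header.get("yllcorner", 0.0),
        nodata=nodata,
    )


def write_ascii_grid(raster: Raster, path, fmt: str = "%.3f") -> None:
    nrows, ncols = raster.shape
    out = np.where(np.isnan(raster.data), raster.nodata, raster.data)
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {raster.xll:g}\n"
        f"yllcorner {raster.yll:g}\n"
        f"cellsize {raster.cellsize:g}\n"
        f"nodata_value {raster.nodata:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt=fmt)
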