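"""DEM preparation, projection through lookup tables, tide-normalized
habitat classification and area accounting.

Habitat classes are assigned on the tide-relative elevation
z* = (E − MSL_t)/(MHHW_t − MSL_t), with the tidal frame raised by the
scenario's cumulative rise at each snapshot year (the MSL–MHHW offset is
held constant).  Class intervals are half-open, lower-inclusive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .forcing import TidalDatums
from .mem import relative_elevation
from .params import HabitatThresholds
from .raster import Raster, RasterError
from .scenarios import ElevationLookup, lookup_elevation

__all__ = [
    "CLASS_NAMES",
    "prepare_dem",
    "apply_mask",
    "project_dem",
    "classify",
    "area_table",
    "area_table_from_counts",
]

#: integer class codes in a classified raster (NaN = masked/nodata)
CLASS_NAMES = ("unvegetated", "low marsh", "mid/high marsh", "upland")

#: DEM elevation cap, cm NAVD88: higher cells are outside the analysis
DEM_CAP_CM = 390.0

#: allowed band for the vegetation-bias offset raster, cm
OFFSET_BAND_CM = (0.0, 70.0)


def prepare_dem(
    raw_dem: Raster,
    offset: Raster | None = None,
    cap_cm: float = DEM_CAP_CM,
) -> Raster:
    """Analysis-ready DEM: offset-corrected, capped, integer centimetres.

    The optional offset raster (a generic stand-in for vegetation-bias
    corrections of LiDAR surfaces) is clamped to 0–70 cm and subtracted.
    Cells above *cap_cm* become nodata; remaining values are rounded up to
    the nearest whole centimetre.
    """
    data = raw_dem.data.copy()
    if offset is not None:
        if not raw_dem.aligned_with(offset):
            raise RasterError("offset raster does not align with the DEM")
        off = np.clip(
            np.nan_to_num(offset.data, nan=0.0), *OFFSET_BAND_CM
        )
        data = data - off
    data[data > cap_cm] = np.nan
    data = np.ceil(data)
    return raw_dem.with_data(data)


def apply_mask(dem: Raster, channel_mask: Raster) -> Raster:
    """Exclude masked cells (mask value 1) from all downstream accounting."""
    if not dem.aligned_with(channel_mask):
        raise RasterError("channel mask does not align with the DEM")
    data = dem.data.copy()
    data[np.nan_to_num(channel_mask.data, nan=0.0) >= 0.5] = np.nan
    return dem.with_data(data)


def project_dem(dem: Raster, lookup: ElevationLookup, year: int) -> Raster:
    """Per-pixel substitution of projected elevations for a snapshot year.

    Masked/nodata cells are preserved.  Year 0 is the identity mapping.
    """
    data = dem.data
    valid = ~np.isnan(data)
    out = np.full(data.shape, np.nan)
    if valid.any():
        out[valid] = lookup_elevation(
            lookup, data[valid].astype(int), year
        )
    return dem.with_data(out)


def classify(
    dem_t: Raster,
    datums_t: TidalDatums,
    thresholds: HabitatThresholds,
) -> Raster:
    """Habitat-class raster from a (projected) DEM and same-year datums.

    Codes: 0 unvegetated, 1 low marsh, 2 mid/high marsh, 3 upland;
    NaN where the input is masked/nodata.  Boundaries are lower-inclusive:
    a pixel exactly at a class's lower bound belongs to that class.
    """
    z = relative_elevation(dem_t.data, datums_t)
    cls = np.full(z.shape, np.nan)
    valid = ~np.isnan(z)
    zv = z[valid]
    code = np.zeros(zv.shape)
    code[zv >= thresholds.unveg_low] = 1
    code[zv >= thresholds.low_mid] = 2
    code[zv >= thresholds.mid_upland] = 3
    cls[valid] = code
    return dem_t.with_data(cls)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


def area_table_from_counts(
    counts, pixel_area_m2: float = 1.0
) -> pd.DataFrame:
    """Area table from per-class pixel counts.

    Returns one row per habitat class with area in hectares, the exact
    percentage of the classified total, and the integer percentage
    (round-half-up) as conventionally reported.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (len(CLASS_NAMES),):
        raise ValueError(f"expected {len(CLASS_NAMES)} class counts")
    total = counts.sum()
    if total == 0:
        raise ValueError("no analyzable pixels")
    area_ha = counts * pixel_area_m2 / 1.0e4
    pct = 100.0 * counts / total
    return pd.DataFrame(
        {
            "class": CLASS_NAMES,
            "area_ha": area_ha,
            "percent_exact": pct,
            "percent": _round_half_up(pct),
        }
    )


def area_table(habitat: Raster, pixel_area_m2: float | None = None) -> pd.DataFrame:
    """Per-class area (ha) and percent cover of a classified raster."""
    if pixel_area_m2 is None:
        pixel_area_m2 = habitat.pixel_area_m2
    valid = ~np.isnan(habitat.data)
    codes = habitat.data[valid].astype(int)
    counts = np.bincount(codes, minlength=len(CLASS_NAMES))
    return area_table_from_counts(counts, pixel_area_m2)


def habitat_shares(habitat: Raster) -> dict[str, float]:
    """Exact percent cover per class, keyed by class name."""
    tab = area_table(habitat)
    return dict(zip(tab["class"], tab["percent_exact"]))
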