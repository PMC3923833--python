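"""Calibration: biomass-parabola fitting, histogram fallback, hindcast
verification against dated cores, and habitat-stability checks.

The parabola fit is an ordinary least-squares quadratic of biomass on
tide-relative elevation using vegetated (biomass > 0) samples only; its
roots give the vegetation limits and its vertex the peak biomass and its
elevation.  The hindcast runs the cohort model for a century at the
historic sea-level-rise rate and compares mean accretion and soil profiles
to core observations, ratio-style.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .forcing import Scenario, hindcast_scenario, sea_level
from .mem import relative_elevation, run_mem, soil_profile
from .params import SiteParams
from .raster import Raster
from .scenarios import ElevationLookup
from .spatial import area_table, classify, project_dem

__all__ = [
    "FittedParabola",
    "fit_biomass_parabola",
    "peak_from_histogram",
    "HindcastReport",
    "hindcast_check",
    "StabilityReport",
    "stability_check",
]


class CalibrationError(ValueError):
    pass


@dataclass
class FittedParabola:
    """OLS quadratic fit of biomass on z* and the derived biotic inputs."""

    z_min: float
    z_peak: float
    z_max: float
    b_max: float
    coeffs: tuple[float, float, float]  # (c0, c1, c2) for c0 + c1 z + c2 z²
    r_squared: float
    n_used: int
    se_coeffs: tuple[float, float, float]

    def predict(self, z):
        c0, c1, c2 = self.coeffs
        z = np.asarray(z, dtype=float)
        return c0 + c1 * z + c2 * z * z


def fit_biomass_parabola(samples: pd.DataFrame) -> FittedParabola:
    """Fit the biomass–elevation parabola from field-style samples.

    *samples* needs columns ``z_star`` and ``biomass_g_m2``.  Only
    vegetated records (biomass > 0) enter the least-squares fit;
    zero-biomass records outside the limits are informative about the
    window but would bias the quadratic.  Fits with non-negative curvature,
    complex roots, or roots extrapolating beyond the vegetated data range
    by more than 50% of its span are rejected.
    """
    for col in ("z_star", "biomass_g_m2"):
        if col not in samples.columns:
            raise CalibrationError(f"samples missing column {col!r}")
    if len(samples) < 6:
        raise CalibrationError("need at least 6 samples")
    veg = samples[samples["biomass_g_m2"] > 0]
    if veg.empty:
        raise CalibrationError("no vegetated samples")
    z = veg["z_star"].to_numpy(dtype=float)
    b = veg["biomass_g_m2"].to_numpy(dtype=float)
    X = sm.add_constant(np.column_stack([z, z * z]))
    res = sm.OLS(b, X).fit()
    c0, c1, c2 = res.params
    if c2 >= 0:
        raise CalibrationError(
            "non-concave fit: no interior biomass optimum in the data"
        )
    disc = c1 * c1 - 4.0 * c2 * c0
    if disc <= 0:
        raise CalibrationError("fitted quadratic has no real roots")
    r1 = (-c1 + np.sqrt(disc)) / (2.0 * c2)
    r2 = (-c1 - np.sqrt(disc)) / (2.0 * c2)
    z_min_fit, z_max_fit = sorted((r1, r2))
    span = z.max() - z.min()
    if span <= 0:
        raise CalibrationError("vegetated samples span zero elevation range")
    if (z.min() - z_min_fit) > 0.5 * span or (z_max_fit - z.max()) > 0.5 * span:
        raise CalibrationError(
            "fitted vegetation limits extrapolate more than 50% beyond "
            "the sampled elevation range"
        )
    z_peak = -c1 / (2.0 * c2)
    b_max = float(c0 + c1 * z_peak + c2 * z_peak * z_peak)
    return FittedParabola(
        z_min=float(z_min_fit),
        z_peak=float(z_peak),
        z_max=float(z_max_fit),
        b_max=b_max,
        coeffs=(float(c0), float(c1), float(c2)),
        r_squared=float(res.rsquared),
        n_used=int(len(veg)),
        se_coeffs=tuple(float(s) for s in res.bse),
    )


def peak_from_histogram(
    samples: pd.DataFrame, species_z: dict[str, float]
) -> tuple[float, float]:
    """Histogram fallback when biomass and elevation were not co-located.

    *samples* needs columns ``species`` and ``biomass_g_m2``.  The species
    with the highest mean biomass sets b_max; its elevation (supplied from
    site knowledge via *species_z*) sets z_peak.  Ties break by species
    label order, with a warning.
    """
    for col in ("species", "biomass_g_m2"):
        if col not in samples.columns:
            raise CalibrationError(f"samples missing column {col!r}")
    if samples.empty:
        raise CalibrationError("no samples")
    means = samples.groupby("species")["biomass_g_m2"].mean()
    top = means[means == means.max()]
    if len(top) > 1:
        warnings.warn(
            f"tied peak-biomass species {sorted(top.index)}; choosing "
            f"{sorted(top.index)[0]} by label order",
            stacklevel=2,
        )
    species = sorted(top.index)[0]
    if species not in species_z:
        raise CalibrationError(
            f"no elevation supplied for modal species {species!r}"
        )
    return float(species_z[species]), float(means.max())


@dataclass
class HindcastReport:
    """Per-core comparison of modeled vs observed accretion and profiles."""

    table: pd.DataFrame
    mean_ratio: float
    core_band: tuple[float, float]
    mean_band: tuple[float, float]

    @property
    def passed(self) -> bool:
        lo, hi = self.core_band
        cores_ok = self.table["ratio"].between(lo, hi).all()
        mlo, mhi = self.mean_band
        return bool(cores_ok and mlo <= self.mean_ratio <= mhi)

    def to_text(self) -> str:
        lines = [
            "Hindcast check (constant historic SLR, current SSC)",
            self.table.to_string(index=False, float_format="%.4f"),
            f"mean modeled/observed ratio: {self.mean_ratio:.4f} "
            f"(band {self.mean_band})",
            f"verdict: {'PASS' if self.passed else 'FAIL'}",
        ]
        return "\n".join(lines)


def hindcast_check(
    site: SiteParams,
    cores: pd.DataFrame,
    core_band: tuple[float, float] = (0.5, 2.0),
    mean_band: tuple[float, float] = (0.8, 1.25),
) -> HindcastReport:
    """Run the century hindcast at each core elevation and compare.

    *cores* is the long-format core table (one row per depth bin) with
    columns core_id, elevation_cm, depth bins, bulk_density_g_cm3, pct_om
    and accretion_cm_yr.  The modeled rate is net elevation change over
    100 years divided by 100; profiles are compared bin-by-bin as RMSE.
    """
    needed = {
        "core_id", "elevation_cm", "bulk_density_g_cm3", "pct_om",
        "accretion_cm_yr",
    }
    missing = needed - set(cores.columns)
    if missing:
        raise CalibrationError(f"core table missing columns: {missing}")
    scen = Scenario(hindcast_scenario(), "high", site.physical.ssc)
    bin_cm = None
    if {"depth_top_cm", "depth_bottom_cm"} <= set(cores.columns):
        first = cores.iloc[0]
        bin_cm = float(first["depth_bottom_cm"] - first["depth_top_cm"])
    rows = []
    for core_id, grp in cores.groupby("core_id", sort=True):
        e0 = float(grp["elevation_cm"].iloc[0])
        z0 = float(relative_elevation(e0, site.datums))
        if not (0.0 <= e0 <= 380.0) or not (
            site.biotic.z_min <= z0 <= site.biotic.z_max
        ):
            raise CalibrationError(
                f"{core_id}: elevation {e0:g} cm (z*={z0:.2f}) outside the "
                "vegetated model range"
            )
        traj = run_mem(e0, scen, site, horizon=100)
        modeled = (traj.elevation_at(100) - traj.elevation_at(0)) / 100.0
        observed = float(grp["accretion_cm_yr"].iloc[0])
        prof = soil_profile(traj.column, bin_cm=bin_cm or 2.0)
        n = min(len(prof), len(grp))
        bd_rmse = float(
            np.sqrt(np.mean(
                (prof["bulk_density_g_cm3"].to_numpy()[:n]
                 - grp["bulk_density_g_cm3"].to_numpy()[:n]) ** 2
            ))
        )
        om_rmse = float(
            np.sqrt(np.mean(
                (prof["pct_om"].to_numpy()[:n]
                 - grp["pct_om"].to_numpy()[:n]) ** 2
            ))
        )
        rows.append(
            {
                "core_id": core_id,
                "elevation_cm": e0,
                "modeled_cm_yr": modeled,
                "observed_cm_yr": observed,
                "ratio": modeled / observed if observed else np.inf,
                "bd_rmse_g_cm3": bd_rmse,
                "om_rmse_pct": om_rmse,
            }
        )
    table = pd.DataFrame(rows)
    return HindcastReport(
        table=table,
        mean_ratio=float(table["ratio"].mean()),
        core_band=core_band,
        mean_band=mean_band,
    )


@dataclass
class StabilityReport:
    """Habitat-share change over a century under the historic SLR rate."""

    table: pd.DataFrame
    tolerance_points: float

    @property
    def stable(self) -> bool:
        return bool(
            (self.table["change_points"].abs() < self.tolerance_points).all()
        )


def stability_check(
    site: SiteParams,
    lookup: ElevationLookup,
    dem: Raster,
    tolerance_points: float = 10.0,
) -> StabilityReport:
    """Do current habitat distributions persist under 24 cm/century?

    Classifies the prepared DEM at year 0 and at year 100 (projected
    through *lookup*, datums risen accordingly) and reports the per-class
    change in percent cover.  The site passes if every class changes by
    less than *tolerance_points* percentage points.
    """
    scen = lookup.scenario
    t0 = area_table(classify(dem, site.datums, site.thresholds))
    rise = sea_level(100.0, scen.slr)
    dem100 = project_dem(dem, lookup, 100)
    t100 = area_table(
        classify(dem100, site.datums.at_year(rise), site.thresholds)
    )
    table = pd.DataFrame(
        {
            "class": t0["class"],
            "percent_y0": t0["percent_exact"],
            "percent_y100": t100["percent_exact"],
        }
    )
    table["change_points"] = table["percent_y100"] - table["percent_y0"]
    return StabilityReport(table=table, tolerance_points=tolerance_points)
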