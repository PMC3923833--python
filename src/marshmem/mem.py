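"""Zero-dimensional soil-cohort marsh accretion model.

Each model year deposits one cohort of mineral sediment on the surface,
allocates belowground organic production over the existing cohorts with an
exponential root profile, decays every labile pool, and recomputes surface
elevation from the self-packing volumes of all cohorts.  The feedback loop —
elevation sets inundation and biomass, which set deposition, which sets
elevation — is what lets a marsh track (or fail to track) rising sea level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forcing import Scenario, TidalDatums, sea_level
from .params import BioticParams, PhysicalParams, SiteParams

__all__ = [
    "relative_elevation",
    "biomass",
    "mineral_deposition",
    "organic_production",
    "distribute_roots",
    "bulk_density",
    "SoilColumn",
    "Trajectory",
    "step_year",
    "run_mem",
    "soil_profile",
    "SNAPSHOT_YEARS",
]

#: snapshot years retained by the scenario engine (plus year 0)
SNAPSHOT_YEARS = (20, 50, 70, 100)

#: calendar year corresponding to model year 0
BASE_CALENDAR_YEAR = 2010

#: mg/L → g/cm³
_MG_L_TO_G_CM3 = 1.0e-6

#: g/m² → g/cm²
_G_M2_TO_G_CM2 = 1.0e-4


def relative_elevation(e_cm: float, datums: TidalDatums):
    """Tide-normalized elevation z* = (e − MSL)/(MHHW − MSL)."""
    rng = datums.range
    if rng <= 0:
        raise ValueError("MHHW must exceed MSL")
    return (np.asarray(e_cm, dtype=float) - datums.msl) / rng


def _parabola_coeffs(p: BioticParams) -> tuple[float, float, float]:
    """Coefficients (a, b, c) of the unique quadratic through
    (z_min, 0), (z_peak, b_max), (z_max, 0)."""
    # through the two roots: B(z) = a·(z − z_min)(z − z_max)
    denom = (p.z_peak - p.z_min) * (p.z_peak - p.z_max)
    if denom == 0:
        raise ValueError("degenerate biomass parabola geometry")
    a = p.b_max / denom
    b = -a * (p.z_min + p.z_max)
    c = a * p.z_min * p.z_max
    return a, b, c


def biomass(z_star, p: BioticParams):
    """Aboveground biomass (g/m²) at tide-relative elevation z*.

    The unique quadratic through (z_min, 0), (z_peak, b_max), (z_max, 0),
    clamped to zero outside the vegetated window and never negative.  When
    z_peak is off-centre the quadratic's vertex exceeds b_max; the curve is
    deliberately not clipped there, only at zero.
    """
    a, b, c = _parabola_coeffs(p)
    z = np.asarray(z_star, dtype=float)
    val = a * z * z + b * z + c
    val = np.where((z < p.z_min) | (z > p.z_max), 0.0, val)
    val = np.maximum(val, 0.0)
    return float(val) if val.ndim == 0 else val


def mineral_deposition(
    e_cm: float,
    datums_t: TidalDatums,
    b_g_m2: float,
    phys: PhysicalParams,
    biotic: BioticParams,
) -> float:
    """Annual mineral deposition, g/cm²/yr.

    Each of n_tides floods carries a water column of depth D = MHHW(t) − e
    at concentration C; the captured fraction is settling, min(1, w_s/D),
    plus biomass trapping q_trap·(b/b_max), capped at one.
    """
    depth = max(0.0, datums_t.mhhw - e_cm)
    if depth == 0.0:
        return 0.0
    conc = phys.ssc * _MG_L_TO_G_CM3
    settle = min(1.0, phys.w_s / depth)
    rel_b = b_g_m2 / biotic.b_max if biotic.b_max > 0 else 0.0
    capture = min(1.0, settle + phys.q_trap * rel_b)
    return conc * depth * phys.n_tides * capture


def organic_production(b_g_m2: float, p: BioticParams) -> tuple[float, float]:
    """Annual belowground production split (refractory, labile), g/cm²/yr."""
    if b_g_m2 < 0:
        raise ValueError("biomass must be nonnegative")
    total = p.rsr * p.turnover * b_g_m2 * _G_M2_TO_G_CM2
    return p.f_ref * total, (1.0 - p.f_ref) * total


def bulk_density(loi, k_org: float, k_min: float):
    """Dry bulk density (g/cm³) from organic fraction by ideal mixing.

    1/ρ = loi/k_org + (1 − loi)/k_min, with k_org and k_min the
    self-packing densities of pure organic and pure mineral soil.
    """
    f = np.asarray(loi, dtype=float)
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("loi must lie in [0, 1]")
    rho = 1.0 / (f / k_org + (1.0 - f) / k_min)
    return float(rho) if rho.ndim == 0 else rho


def distribute_roots(
    thickness_cm: np.ndarray, d95: float
) -> np.ndarray:
    """Fraction of belowground production allocated to each cohort.

    Cohorts are ordered youngest (surface) first; allocation integrates the
    exponential root density λe^{−λd}, λ = ln(20)/d95, over each cohort's
    depth interval.  The tail below the column bottom goes to the bottom
    cohort, so the fractions sum to one exactly.
    """
    if d95 <= 0:
        raise ValueError("d95 must be positive")
    th = np.asarray(thickness_cm, dtype=float)
    if th.size == 0:
        raise ValueError("column has no cohorts")
    lam = math.log(20.0) / d95
    bounds = np.concatenate([[0.0], np.cumsum(th)])
    cdf = -np.expm1(-lam * bounds)  # 1 − e^{−λd}, stable for small λd
    frac = np.diff(cdf)
    frac[-1] += 1.0 - cdf[-1]  # tail below the column bottom
    return frac


@dataclass
class SoilColumn:
    """Cohort stack above the pre-existing substrate.

    Arrays are ordered youngest first.  ``base_cm`` is the elevation of the
    substrate surface at the start of the run; the marsh surface sits at
    base_cm plus the summed cohort volumes.  Cumulative totals support
    exact mass-balance audits.
    """

    base_cm: float
    phys: PhysicalParams
    year: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    m_mineral: np.ndarray = field(default_factory=lambda: np.empty(0))
    m_labile: np.ndarray = field(default_factory=lambda: np.empty(0))
    m_refractory: np.ndarray = field(default_factory=lambda: np.empty(0))
    total_mineral_deposited: float = 0.0
    total_organic_produced: float = 0.0
    total_organic_decayed: float = 0.0

    def __len__(self) -> int:
        return len(self.year)

    def volumes(self) -> np.ndarray:
        """Per-cohort height (cm per unit area) by self-packing densities."""
        return (
            self.m_mineral / self.phys.k_min
            + (self.m_labile + self.m_refractory) / self.phys.k_org
        )

    @property
    def height_cm(self) -> float:
        return float(self.volumes().sum())

    @property
    def elevation_cm(self) -> float:
        return self.base_cm + self.height_cm

    def add_cohort(self, year: int, m_mineral: float) -> None:
        """Push this year's surface cohort (youngest-first ordering)."""
        self.year = np.concatenate([[year], self.year])
        self.m_mineral = np.concatenate([[m_mineral], self.m_mineral])
        self.m_labile = np.concatenate([[0.0], self.m_labile])
        self.m_refractory = np.concatenate([[0.0], self.m_refractory])
        self.total_mineral_deposited += m_mineral

    def add_organic(self, refractory: float, labile: float, d95: float) -> None:
        frac = distribute_roots(self.volumes(), d95)
        self.m_refractory = self.m_refractory + refractory * frac
        self.m_labile = self.m_labile + labile * frac
        self.total_organic_produced += refractory + labile

    def decay(self, k_decay: float) -> None:
        """One year of first-order decay of every labile pool."""
        retained = math.exp(-k_decay)
        self.total_organic_decayed += float(
            self.m_labile.sum() * (1.0 - retained)
        )
        self.m_labile = self.m_labile * retained

    @property
    def organic_stored(self) -> float:
        return float(self.m_labile.sum() + self.m_refractory.sum())

    @property
    def mineral_stored(self) -> float:
        return float(self.m_mineral.sum())


@dataclass
class Trajectory:
    """Per-year output of one model run at one starting elevation."""

    table: pd.DataFrame
    column: SoilColumn
    scenario: Scenario

    def elevation_at(self, year: int) -> float:
        if year not in self.table.index:
            raise KeyError(f"year {year} not in trajectory")
        return float(self.table.loc[year, "elevation_cm_navd88"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="year")


def step_year(
    column: SoilColumn,
    year: int,
    datums_t: TidalDatums,
    scenario: Scenario,
    site: SiteParams,
) -> dict:
    """Advance the column by one year; returns the year's diagnostics.

    Order of operations: z* from the current surface and this year's
    datums → biomass → mineral cohort deposition → organic production
    allocated by the root profile → decay of all labile pools → new
    surface elevation from summed cohort volumes.
    """
    phys = PhysicalParams(
        ssc=scenario.ssc_mg_l,
        w_s=site.physical.w_s,
        q_trap=site.physical.q_trap,
        n_tides=site.physical.n_tides,
        k_org=site.physical.k_org,
        k_min=site.physical.k_min,
    )
    e_prev = column.elevation_cm
    z = float(relative_elevation(e_prev, datums_t))
    b = biomass(z, site.biotic)
    dep = mineral_deposition(e_prev, datums_t, b, phys, site.biotic)
    column.add_cohort(year, dep)
    refractory, labile = organic_production(b, site.biotic)
    column.add_organic(refractory, labile, site.biotic.d95)
    column.decay(site.biotic.k_decay)
    e_new = column.elevation_cm
    if not math.isfinite(e_new):
        raise FloatingPointError(f"non-finite elevation at year {year}")
    return {
        "elevation_cm_navd88": e_new,
        "z_star": z,
        "biomass_g_m2": b,
        "accretion_cm": e_new - e_prev,
        "mineral_g_cm2": dep,
        "organic_g_cm2": refractory + labile,
    }


def run_mem(
    e0_cm: float,
    scenario: Scenario,
    site: SiteParams,
    horizon: int = 100,
) -> Trajectory:
    """Run the cohort model for *horizon* years from starting elevation e0.

    Datums are raised annually along the scenario's SLR curve before
    deposition.  For horizons beyond 100 years (equilibrium studies) the
    curve's instantaneous rate at year 100 is extended linearly.
    """
    if horizon < 0:
        raise ValueError("horizon must be nonnegative")
    phys = site.physical
    column = SoilColumn(base_cm=float(e0_cm), phys=phys)
    records = {
        0: {
            "elevation_cm_navd88": float(e0_cm),
            "z_star": float(relative_elevation(e0_cm, site.datums)),
            "biomass_g_m2": biomass(
                float(relative_elevation(e0_cm, site.datums)), site.biotic
            ),
            "accretion_cm": 0.0,
            "mineral_g_cm2": 0.0,
            "organic_g_cm2": 0.0,
        }
    }
    for year in range(1, horizon + 1):
        if year <= 100:
            rise = sea_level(year, scenario.slr)
        else:
            end_rate = scenario.slr.r0 + 2.0 * scenario.slr.accel * 100.0
            rise = scenario.slr.s100 + end_rate * (year - 100)
        datums_t = site.datums.at_year(rise)
        records[year] = step_year(column, year, datums_t, scenario, site)
        # z* recorded against the datums in force that year
        records[year]["z_star"] = float(
            relative_elevation(records[year]["elevation_cm_navd88"], datums_t)
        )
    table = pd.DataFrame.from_dict(records, orient="index")
    table.index.name = "year"
    return Trajectory(table=table, column=column, scenario=scenario)


def soil_profile(column: SoilColumn, bin_cm: float = 2.0) -> pd.DataFrame:
    """Depth profile of bulk density and %OM, mass-weighted into bins.

    Bins run from the surface downward; the last bin may be partial (its
    true height is reported) so that Σ(bin BD × bin height) equals the
    column's total mass exactly.
    """
    if bin_cm <= 0:
        raise ValueError("bin_cm must be positive")
    if len(column) == 0:
        raise ValueError("empty soil column")
    vol = column.volumes()
    total_h = float(vol.sum())
    if total_h == 0:
        raise ValueError("zero-height soil column")
    tops = np.concatenate([[0.0], np.cumsum(vol)])[:-1]
    bottoms = tops + vol
    organic = column.m_labile + column.m_refractory
    mass = column.m_mineral + organic

    n_bins = int(np.ceil(total_h / bin_cm))
    rows = []
    for i in range(n_bins):
        d0, d1 = i * bin_cm, min((i + 1) * bin_cm, total_h)
        # overlap of each cohort's depth interval with the bin
        ov = np.clip(np.minimum(bottoms, d1) - np.maximum(tops, d0), 0.0, None)
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(vol > 0, ov / np.where(vol > 0, vol, 1.0), 0.0)
        m_bin = float((mass * w).sum())
        om_bin = float((organic * w).sum())
        h = d1 - d0
        rows.append(
            {
                "depth_top_cm": d0,
                "depth_bottom_cm": d1,
                "height_cm": h,
                "bulk_density_g_cm3": m_bin / h if h > 0 else np.nan,
                "pct_om": 100.0 * om_bin / m_bin if m_bin > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)
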