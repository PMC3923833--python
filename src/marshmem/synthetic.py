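"""Synthetic field data with the statistical structure the pipeline assumes.

Every generator is a pure function of its parameters and an explicit integer
seed: mixed semidiurnal tides, marsh-platform DEMs (island or
upland-adjacent templates) with dendritic channels, parabolic
biomass–elevation samples, and soil-core profiles consistent with a known
accretion history.  The generating truth is recorded alongside each
artifact so calibration can be tested as parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .forcing import Scenario, TidalDatums, WaterLevelSeries, hindcast_scenario
from .mem import biomass, run_mem, soil_profile
from .params import BioticParams, SiteParams
from .raster import Raster

__all__ = [
    "SiteTemplate",
    "SyntheticTruth",
    "make_tides",
    "make_dem",
    "make_biomass_samples",
    "make_core_profiles",
    "make_site_directory",
]

#: default tidal constituents (amplitude cm, period h, phase rad):
#: a principal semidiurnal and a diurnal constituent give the mixed,
#: predominantly semidiurnal regime of the study estuary
DEFAULT_CONSTITUENTS = ((60.0, 12.42, 0.0), (25.0, 23.93, 1.0))


@dataclass(frozen=True)
class SiteTemplate:
    """Geometry of a synthetic site.

    layout : "island" (broad low-marsh fringe, no upland) or
        "upland-adjacent" (narrow shore fringe plus an upland ramp).
    platform_z : modal tide-relative elevation of the marsh plain.
    fringe_px : width of the low-marsh band, pixels.
    rim_px : width of the outer mudflat rim (island layout), pixels.
    ramp_frac : fraction of columns occupied by the upland ramp
        (upland-adjacent layout).
    ramp_slope : ramp steepness, z* per pixel.
    channel_density : main channels per 100 columns.
    extent : (nrows, ncols), 1 m pixels.
    noise_sd_cm : sd of pixel-scale Gaussian roughness.
    """

    layout: str = "island"
    platform_z: float = 0.8
    fringe_px: int = 14
    rim_px: int = 3
    ramp_frac: float = 0.25
    ramp_slope: float = 0.10
    channel_density: float = 3.0
    extent: tuple[int, int] = (120, 120)
    noise_sd_cm: float = 3.0

    def __post_init__(self) -> None:
        if self.layout not in ("island", "upland-adjacent"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if min(self.extent) <= 0:
            raise ValueError("extent must be positive")


def island_template(**kw) -> SiteTemplate:
    """Island site: broad low marsh, no upland (cf. the island study sites)."""
    return SiteTemplate(layout="island", **kw)


def upland_template(**kw) -> SiteTemplate:
    """Upland-adjacent site: thin shore fringe, ramp rising past the cap."""
    kw.setdefault("fringe_px", 5)
    return SiteTemplate(layout="upland-adjacent", **kw)


@dataclass
class SyntheticTruth:
    """Generating parameters recorded alongside a synthetic artifact."""

    seed: int
    kind: str
    params: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {"seed": self.seed, "kind": self.kind, "params": self.params},
                sort_keys=False,
            )
        )


def make_tides(
    msl_cm: float,
    constituents=DEFAULT_CONSTITUENTS,
    days: float = 35.0,
    interval_min: float = 6.0,
    seed: int = 0,
    noise_sd_cm: float = 0.0,
    start: str = "2010-01-01",
) -> WaterLevelSeries:
    """Mixed-tide stage record: sum of sinusoidal constituents about MSL."""
    if days < 29:
        raise ValueError("need at least 29 days (one lunar month)")
    n = int(days * 24 * 60 / interval_min)
    t0 = np.datetime64(start, "s")
    times = t0 + (np.arange(n) * interval_min * 60).astype("timedelta64[s]")
    t_h = np.arange(n) * interval_min / 60.0
    stage = np.full(n, float(msl_cm))
    for amp, period_h, phase in constituents:
        stage += amp * np.cos(2.0 * np.pi * t_h / period_h + phase)
    if noise_sd_cm > 0:
        rng = np.random.default_rng(seed)
        stage = stage + rng.normal(0.0, noise_sd_cm, n)
    return WaterLevelSeries(times, stage)


def _carve_channels(
    z: np.ndarray, mask: np.ndarray, template: SiteTemplate, rng
) -> None:
    """Dendritic-ish channels: jittered walks from the seaward edge inland,
    each with one branch.  Channel cells are lowered and masked."""
    nrows, ncols = z.shape
    n_chan = int(round(template.channel_density * ncols / 100.0))
    depth_z = -0.5
    for _ in range(n_chan):
        row = int(rng.integers(nrows // 6, 5 * nrows // 6))
        length = int(ncols * rng.uniform(0.3, 0.55))
        branch_at = int(rng.integers(length // 3, max(length // 3 + 1, length)))
        r = row
        for step in range(length):
            c = step  # channels enter from the left (seaward) edge
            r = int(np.clip(r + rng.integers(-1, 2), 0, nrows - 1))
            z[r, c] = depth_z
            mask[r, c] = 1.0
            if step == branch_at:
                rb = r
                for bstep in range(length // 2):
                    cb = c + bstep
                    if cb >= ncols:
                        break
                    rb = int(np.clip(rb + rng.integers(0, 2), 0, nrows - 1))
                    z[rb, cb] = depth_z
                    mask[rb, cb] = 1.0


def make_dem(
    template: SiteTemplate,
    datums: TidalDatums,
    seed: int = 0,
) -> tuple[Raster, Raster, SyntheticTruth]:
    """Synthetic DEM (cm NAVD88, float) and 0/1 channel-mask raster.

    Island layout: a mid/high platform ringed by a broad low-marsh fringe
    and a mudflat rim, no cells above the upland threshold.
    Upland-adjacent layout: narrow shore fringe, broad platform, and a
    linear upland ramp that rises past marsh elevations (the tallest cells
    exceed the analysis cap and drop out during preparation).
    """
    rng = np.random.default_rng(seed)
    nrows, ncols = template.extent
    z = np.empty((nrows, ncols))
    mask = np.zeros((nrows, ncols))

    if template.layout == "island":
        ci, cj = (nrows - 1) / 2.0, (ncols - 1) / 2.0
        ii, jj = np.indices((nrows, ncols))
        # square-island distance to the nearest edge, in pixels
        d_edge = np.minimum.reduce(
            [ii, jj, nrows - 1 - ii, ncols - 1 - jj]
        ).astype(float)
        rim, fringe = template.rim_px, template.fringe_px
        z[:] = template.platform_z
        in_fringe = (d_edge >= rim) & (d_edge < rim + fringe)
        if fringe > 0:
            frac = (d_edge[in_fringe] - rim) / fringe  # 0 outer, 1 inner
            z[in_fringe] = 0.0 + frac * (0.62 - 0.0)
        in_rim = d_edge < rim
        if rim > 0:
            z[in_rim] = -0.6 + (d_edge[in_rim] / rim) * 0.55
    else:
        z[:] = template.platform_z
        fringe = template.fringe_px
        if fringe > 0:
            cols = np.arange(ncols)
            frac = np.clip(cols / max(fringe, 1), 0.0, 1.0)
            z[:] = 0.25 + frac * (template.platform_z - 0.25)
            z[:, fringe:] = template.platform_z
        ramp_w = int(round(template.ramp_frac * ncols))
        if ramp_w > 0:
            ramp_cols = np.arange(ncols - ramp_w, ncols)
            rise = (ramp_cols - (ncols - ramp_w)) * template.ramp_slope
            z[:, ramp_cols] = template.platform_z + 0.1 + rise

    _carve_channels(z, mask, template, rng)

    elev_cm = datums.msl + z * datums.range
    if template.noise_sd_cm > 0:
        elev_cm = elev_cm + rng.normal(0.0, template.noise_sd_cm, z.shape)

    truth = SyntheticTruth(
        seed=seed,
        kind="dem",
        params={"template": asdict(template), "msl": datums.msl,
                "mhhw": datums.mhhw},
    )
    return Raster(elev_cm), Raster(mask), truth


def make_biomass_samples(
    biotic: BioticParams,
    n: int = 500,
    noise_sd: float = 200.0,
    seed: int = 0,
    pad: float = 0.15,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Biomass–elevation samples: the truth parabola plus truncated noise.

    Elevations are drawn uniformly over the vegetated window padded by
    *pad* on both sides, so some samples fall outside the limits and carry
    (near-)zero biomass, as field surveys do.
    """
    if n < 6:
        raise ValueError("need at least 6 samples")
    rng = np.random.default_rng(seed)
    z = rng.uniform(biotic.z_min - pad, biotic.z_max + pad, n)
    b_true = biomass(z, biotic)
    b = b_true if noise_sd == 0 else np.maximum(
        0.0, b_true + rng.normal(0.0, noise_sd, n)
    )
    df = pd.DataFrame({"z_star": z, "biomass_g_m2": b})
    truth = SyntheticTruth(
        seed=seed,
        kind="biomass",
        params={
            "z_min": biotic.z_min, "z_peak": biotic.z_peak,
            "z_max": biotic.z_max, "b_max": biotic.b_max,
            "noise_sd": noise_sd, "n": n,
        },
    )
    return df, truth


#: default tide-relative core elevations, spread across the vegetated band
DEFAULT_CORE_Z = (0.45, 0.55, 0.65, 0.75, 0.85, 0.95)


def make_core_profiles(
    site: SiteParams,
    n_cores: int = 6,
    noise_frac: float = 0.0,
    seed: int = 0,
    bin_cm: float = 2.0,
    core_z=DEFAULT_CORE_Z,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Soil-core profiles from the model's own constant-rate hindcast.

    Each core is the depth profile of a century-long run at the historic
    SLR rate and current SSC, with the run's mean accretion rate embedded
    as the dated-core estimate; multiplicative noise emulates measurement
    error.  With zero noise the cores are exactly self-consistent with the
    model, which anchors the calibration tests.
    """
    rng = np.random.default_rng(seed)
    scen = Scenario(hindcast_scenario(), "high", site.physical.ssc)
    frames = []
    true_rates = {}
    for k in range(n_cores):
        zc = core_z[k % len(core_z)]
        e0 = site.datums.msl + zc * site.datums.range
        traj = run_mem(e0, scen, site, horizon=100)
        rate = (traj.elevation_at(100) - traj.elevation_at(0)) / 100.0
        prof = soil_profile(traj.column, bin_cm=bin_cm)
        obs_rate = rate
        if noise_frac > 0:
            prof = prof.copy()
            prof["bulk_density_g_cm3"] *= 1.0 + rng.normal(
                0.0, noise_frac, len(prof)
            )
            prof["pct_om"] *= 1.0 + rng.normal(0.0, noise_frac, len(prof))
            prof["pct_om"] = prof["pct_om"].clip(0.0, 100.0)
            obs_rate = rate * (1.0 + rng.normal(0.0, noise_frac))
        prof.insert(0, "core_id", f"core{k + 1}")
        prof.insert(1, "elevation_cm", e0)
        prof["accretion_cm_yr"] = obs_rate
        frames.append(prof)
        true_rates[f"core{k + 1}"] = rate
    df = pd.concat(frames, ignore_index=True)
    truth = SyntheticTruth(
        seed=seed,
        kind="cores",
        params={
            "true_rates": true_rates,
            "noise_frac": noise_frac,
            "bin_cm": bin_cm,
        },
    )
    return df, truth


def make_site_directory(
    outdir,
    site: SiteParams | None = None,
    template: SiteTemplate | None = None,
    seed: int = 0,
    tide_days: float = 35.0,
    biomass_n: int = 500,
    biomass_noise_sd: float = 200.0,
    core_noise_frac: float = 0.0,
) -> Path:
    """Write a complete runnable example site directory.

    Contents: site.yaml, dem.asc, channel_mask.asc, tides.csv,
    biomass.csv, cores.csv and truth.yaml.
    """
    from .params import default_site

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    site = site or default_site()
    template = template or island_template()
    rng = np.random.default_rng(seed)
    seeds = {k: int(s) for k, s in zip(
        ("dem", "tides", "biomass", "cores"),
        rng.integers(0, 2**31 - 1, 4),
    )}

    site.to_yaml(outdir / "site.yaml")
    dem, mask, dem_truth = make_dem(template, site.datums, seed=seeds["dem"])
    from .raster import write_ascii_grid

    write_ascii_grid(dem, outdir / "dem.asc", fmt="%.1f")
    write_ascii_grid(mask, outdir / "channel_mask.asc", fmt="%d")
    # constituents scaled so the record's MHHW is near the site datum
    half_range = site.datums.range
    const = (
        (0.75 * half_range, 12.42, 0.0),
        (0.31 * half_range, 23.93, 1.0),
    )
    tides = make_tides(
        site.datums.msl, const, days=tide_days, seed=seeds["tides"]
    )
    tides.to_csv(outdir / "tides.csv")
    samples, bio_truth = make_biomass_samples(
        site.biotic, n=biomass_n, noise_sd=biomass_noise_sd,
        seed=seeds["biomass"],
    )
    samples.to_csv(outdir / "biomass.csv", index=False)
    cores, core_truth = make_core_profiles(
        site, noise_frac=core_noise_frac, seed=seeds["cores"]
    )
    cores.to_csv(outdir / "cores.csv", index=False)
    SyntheticTruth(
        seed=seed,
        kind="site",
        params={
            "seeds": seeds,
            "dem": dem_truth.params,
            "biomass": bio_truth.params,
            "cores": core_truth.params,
        },
    ).to_yaml(outdir / "truth.yaml")
    return outdir
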